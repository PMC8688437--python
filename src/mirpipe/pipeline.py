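"""End-to-end pipeline: simulate → quantify → DE → shift → concordance → report.

The pipeline runs over a single flat JSON configuration and one global seed
that cascades to fixed per-component seeds.  Each stage writes TSV outputs
into the run directory and records SHA-256 checksums in a run manifest;
re-running with an identical configuration reproduces identical checksums
for every deterministic stage output.

The bundled demo configuration emulates the study design this package
targets: two cell lines, knockdown vs control, miRNA counts obtained by the
full read-level simulate→trim→map→quantify path, gene counts with a
minority of truly changed genes, and two planted miRNAs whose target genes
carry a repression-release shift.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinstats, diffexpr, io, quant, shift, synthetic

CELL_LINES = ("line1", "line2")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "n_chrom": 2,
        "chrom_len": 20000,
        "n_mirna": 24,
        "mirna_base_count": 300.0,
        "reps_per_group": 2,
        "n_de_mirna_shared": 6,
        "n_de_mirna_unique": 2,
        "de_mirna_lfcs": [-1.5, -2.0, -1.2, 1.3, 1.8, -1.6, 1.1, -1.4, 1.6, -1.1],
        "adapter": "TGGAATTCTCGGGTGCCAAGG",
        "error_rate": 0.005,
        "n_genes": 2500,
        "gene_dispersion": 0.1,
        "frac_de_genes": 0.10,
        "gene_lfc": 1.0,
        "gene_reps_per_group": 3,
        "n_shift_mirnas": 2,
        "targets_per_mirna": 150,
        "delta": 0.5,
        "decoy_targets_per_mirna": 100,
        "clinical_n": 349,
        "auc_target": 0.878,
        "hr_target": 2.0,
    },
    "quant": {"window": 3, "min_len": 18, "max_len": 28},
    "de": {"fdr_threshold": 0.05},
    "shift": {"min_targets": 10, "hit_p": 1e-3, "min_mirna_count": 10},
    "external_inputs": {},
}


def demo_config(seed: int = 0) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    cfg["seed"] = int(seed)
    return cfg


def validate_config(config: dict) -> list[str]:
    """Validate a pipeline configuration; returns a list of violations."""
    v: list[str] = []
    sim = config.get("simulate", {})
    qc = config.get("quant", {})
    de = config.get("de", {})
    sh = config.get("shift", {})
    if not isinstance(config.get("seed"), int):
        v.append("seed must be an integer")
    if qc.get("window", 3) < 0:
        v.append("quant.window must be >= 0")
    if qc.get("min_len", 18) > qc.get("max_len", 28):
        v.append("quant.min_len must be <= quant.max_len")
    if not 0 < de.get("fdr_threshold", 0.05) < 1:
        v.append("de.fdr_threshold must lie in (0, 1)")
    if not 0 <= sim.get("error_rate", 0.0) <= 1:
        v.append("simulate.error_rate must lie in [0, 1]")
    if len(sim.get("adapter", "x" * 8)) < 8:
        v.append("simulate.adapter must be at least 8 nt")
    for key in ("n_chrom", "n_mirna", "n_genes", "clinical_n", "reps_per_group"):
        if sim.get(key, 1) < 1:
            v.append(f"simulate.{key} must be >= 1")
    if sim.get("chrom_len", 200) < 200:
        v.append("simulate.chrom_len must be >= 200")
    if not 0.5 <= sim.get("auc_target", 0.878) <= 1.0:
        v.append("simulate.auc_target must lie in [0.5, 1.0]")
    if sim.get("hr_target", 2.0) <= 0:
        v.append("simulate.hr_target must be positive")
    if sh.get("min_targets", 10) < 1:
        v.append("shift.min_targets must be >= 1")
    for name, path in (config.get("external_inputs") or {}).items():
        if not Path(path).exists():
            v.append(f"external_inputs.{name}: file not found: {path}")
    return v


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage
        self.record = {"stage": stage, "error": message}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()


def _log(stage: str, message: str) -> None:
    print(f"[{time.strftime('%H:%M:%S')}] [{stage}] {message}", flush=True)


def _sample_names(reps: int) -> list[str]:
    return [f"ctrl_{i + 1}" for i in range(reps)] + [f"kd_{i + 1}" for i in range(reps)]


def stage_simulate(config: dict, outdir: Path) -> dict:
    """Generate the full synthetic study into the run directory."""
    sim = config["simulate"]
    seed = config["seed"]
    rng = np.random.default_rng([seed, 97])
    genome = synthetic.make_toy_genome(sim["n_chrom"], sim["chrom_len"], seed)
    loci = synthetic.plant_mirna_loci(genome, sim["n_mirna"], seed=seed)
    io.write_fasta(outdir / "genome.fa", genome.sequences)
    io.write_mirna_gff3(outdir / "mirna_loci.gff3", loci)

    mirna_ids = [loc.mirna_id for loc in loci]
    n_shared = sim["n_de_mirna_shared"]
    n_unique = sim["n_de_mirna_unique"]
    picked = [str(m) for m in rng.choice(mirna_ids, size=n_shared + 2 * n_unique, replace=False)]
    shared = picked[:n_shared]
    unique = {
        CELL_LINES[0]: picked[n_shared : n_shared + n_unique],
        CELL_LINES[1]: picked[n_shared + n_unique :],
    }
    lfc_cycle = sim["de_mirna_lfcs"]
    # the planted shift miRNAs must be repressed so their targets are released
    shift_mirnas = [m for m, l in zip(shared, lfc_cycle) if l < 0][: sim["n_shift_mirnas"]]
    if len(shift_mirnas) < sim["n_shift_mirnas"]:
        raise StageError("simulate", "not enough repressed shared miRNAs for the planted shifts")
    mirna_lfc_truth = {}
    for line in CELL_LINES:
        per_line = {}
        for i, m in enumerate(shared):
            per_line[m] = lfc_cycle[i % len(lfc_cycle)]
        for i, m in enumerate(unique[line]):
            per_line[m] = lfc_cycle[(i + n_shared) % len(lfc_cycle)]
        mirna_lfc_truth[line] = per_line

    reps = sim["reps_per_group"]
    samples = _sample_names(reps)
    base_counts = {
        m: float(np.exp(rng.normal(np.log(sim["mirna_base_count"]), 0.4))) for m in mirna_ids
    }
    fastq_paths = {}
    truth_frames = []
    for li, line in enumerate(CELL_LINES):
        expected = {}
        for s in samples:
            per = {}
            for m in mirna_ids:
                mean = base_counts[m]
                if s.startswith("kd") and m in mirna_lfc_truth[line]:
                    mean *= 2.0 ** mirna_lfc_truth[line][m]
                per[m] = mean
            expected[s] = per
        spec = synthetic.SmallRNASimSpec(
            expected_counts=expected,
            adapter=sim["adapter"],
            error_rate=sim["error_rate"],
            seed=seed * 10 + li,
        )
        reads_per_sample, truth = synthetic.simulate_smallrna_reads(loci, spec, genome)
        for s, reads in reads_per_sample.items():
            path = outdir / f"reads_{line}_{s}.fastq"
            io.write_fastq(path, reads)
            fastq_paths[(line, s)] = path
        truth["cell_line"] = line
        truth_frames.append(truth)
    io.write_tsv(outdir / "smallrna_truth.tsv", pd.concat(truth_frames, ignore_index=True))

    # gene-level matrices with planted repression-release targets
    gene_ids = [f"gene_{i + 1}" for i in range(sim["n_genes"])]
    pool = list(rng.permutation(sim["n_genes"]))
    target_map: dict[str, set[str]] = {}
    cursor = 0
    for m in shift_mirnas:
        target_map[m] = {gene_ids[i] for i in pool[cursor : cursor + sim["targets_per_mirna"]]}
        cursor += sim["targets_per_mirna"]
    for m in shared:
        if m in target_map:
            continue
        target_map[m] = {
            gene_ids[i] for i in pool[cursor : cursor + sim["decoy_targets_per_mirna"]]
        }
        cursor += sim["decoy_targets_per_mirna"]
    target_rows = [
        {"mirna_id": m, "gene_id": g} for m in sorted(target_map) for g in sorted(target_map[m])
    ]
    io.write_tsv(outdir / "target_map.tsv", pd.DataFrame(target_rows))

    all_targets = set().union(*target_map.values())
    delta = {m: sim["delta"] for m in shift_mirnas}
    gene_truth_rows = []
    for li, line in enumerate(CELL_LINES):
        truth = synthetic.default_expression_truth(
            n_genes=sim["n_genes"],
            dispersion=sim["gene_dispersion"],
            group_sizes=(sim["gene_reps_per_group"], sim["gene_reps_per_group"]),
            frac_de=sim["frac_de_genes"],
            de_lfc=sim["gene_lfc"],
            target_map={m: target_map[m] for m in shift_mirnas},
            delta=delta,
            seed=seed * 10 + li + 5,
        )
        truth.gene_ids = gene_ids
        # targets keep their own LFC at 0 so the planted shift is purely delta
        target_idx = [i for i, g in enumerate(gene_ids) if g in all_targets]
        truth.lfc[target_idx] = 0.0
        matrix, _ = synthetic.simulate_count_matrix(truth)
        frame = pd.DataFrame(matrix.counts, index=matrix.feature_ids, columns=matrix.sample_ids)
        frame.index.name = "gene_id"
        io.write_tsv(outdir / f"gene_counts_{line}.tsv", frame, index=True)
        io.write_tsv(
            outdir / f"gene_groups_{line}.tsv",
            pd.DataFrame({"sample_id": matrix.sample_ids, "group": matrix.groups}),
        )
        gene_truth_rows.append(
            pd.DataFrame({"cell_line": line, "gene_id": gene_ids, "true_lfc": truth.lfc})
        )
    io.write_tsv(outdir / "gene_truth.tsv", pd.concat(gene_truth_rows, ignore_index=True))

    clinical = synthetic.simulate_clinical(
        sim["clinical_n"], sim["auc_target"], sim["hr_target"], seed
    )
    io.write_tsv(outdir / "clinical.tsv", clinical)

    truth_summary = pd.DataFrame(
        [
            {"cell_line": line, "mirna_id": m, "true_lfc": l, "shift_mirna": m in shift_mirnas}
            for line in CELL_LINES
            for m, l in sorted(mirna_lfc_truth[line].items())
        ]
    )
    io.write_tsv(outdir / "mirna_truth.tsv", truth_summary)
    _log("simulate", f"{len(loci)} loci, {len(fastq_paths)} FASTQ files, 2 gene matrices")
    return {
        "genome": genome,
        "loci": loci,
        "fastq_paths": fastq_paths,
        "samples": samples,
        "shift_mirnas": shift_mirnas,
        "target_map": target_map,
        "mirna_lfc_truth": mirna_lfc_truth,
    }


def stage_quant(config: dict, outdir: Path, sim_state: dict) -> dict:
    """Quantify every small-RNA sample and assemble per-line count matrices."""
    qc = config["quant"]
    genome, loci = sim_state["genome"], sim_state["loci"]
    adapter = config["simulate"]["adapter"]
    matrices = {}
    for line in CELL_LINES:
        columns = {}
        for s in sim_state["samples"]:
            reads = io.read_fastq(sim_state["fastq_paths"][(line, s)])
            records = quant.quantify_sample(
                reads,
                genome,
                loci,
                adapter,
                window=qc["window"],
                min_len=qc["min_len"],
                max_len=qc["max_len"],
            )
            columns[s] = {rec.mirna_id: rec.abundance for rec in records}
        frame = pd.DataFrame(columns)[sim_state["samples"]]
        frame.index.name = "mirna_id"
        io.write_tsv(outdir / f"mirna_counts_{line}.tsv", frame, index=True)
        groups = ["control" if s.startswith("ctrl") else "knockdown" for s in frame.columns]
        matrices[line] = diffexpr.CountMatrix(
            feature_ids=list(frame.index),
            sample_ids=list(frame.columns),
            counts=frame.to_numpy(),
            groups=groups,
        )
    _log("quant", f"quantified {len(CELL_LINES) * len(sim_state['samples'])} samples")
    return {"mirna_matrices": matrices}


def stage_de(config: dict, outdir: Path, sim_state: dict, quant_state: dict) -> dict:
    """Gene and miRNA differential expression for each cell line."""
    fdr = config["de"]["fdr_threshold"]
    gene_results, mirna_results, summaries = {}, {}, {}
    for line in CELL_LINES:
        frame = io.read_tsv(outdir / f"gene_counts_{line}.tsv", index_col=0)
        groups = ["control" if s.startswith("ctrl") else "knockdown" for s in frame.columns]
        matrix = diffexpr.CountMatrix(
            feature_ids=list(frame.index),
            sample_ids=list(frame.columns),
            counts=frame.to_numpy(),
            groups=groups,
        )
        res, summary, _, phi = diffexpr.de_pipeline(matrix, fdr_threshold=fdr)
        io.write_tsv(outdir / f"gene_de_{line}.tsv", res)
        gene_results[line] = res
        summaries[f"gene_{line}"] = summary | {"dispersion": phi}

        mres, msummary, _, mphi = diffexpr.de_pipeline(quant_state["mirna_matrices"][line], fdr_threshold=fdr)
        io.write_tsv(outdir / f"mirna_de_{line}.tsv", mres)
        mirna_results[line] = mres
        summaries[f"mirna_{line}"] = msummary | {"dispersion": mphi}
    _log("de", f"summaries: {summaries}")
    return {"gene_de": gene_results, "mirna_de": mirna_results, "de_summaries": summaries}


def stage_shift(config: dict, outdir: Path, sim_state: dict, de_state: dict) -> dict:
    """Target CDF-shift tests for the shared DE miRNAs in both cell lines."""
    sh = config["shift"]
    fdr = config["de"]["fdr_threshold"]
    de_sets = {}
    for line in CELL_LINES:
        m = de_state["mirna_de"][line]
        de_sets[line] = set(m.loc[m["FDR"] < fdr, "feature_id"])
    shared = sorted(de_sets[CELL_LINES[0]] & de_sets[CELL_LINES[1]])

    target_map = sim_state["target_map"]
    rows = []
    hits_per_line: dict[str, set[str]] = {line: set() for line in CELL_LINES}
    for line in CELL_LINES:
        gene_de = de_state["gene_de"][line]
        lfc_table = pd.Series(gene_de["logFC"].to_numpy(), index=gene_de["feature_id"])
        mirna_de = de_state["mirna_de"][line].set_index("feature_id")
        for m in shared:
            if m not in target_map:
                continue
            res = shift.target_shift_test(
                m, target_map, lfc_table, float(mirna_de.loc[m, "logFC"]), min_targets=sh["min_targets"]
            )
            rows.append(
                {
                    "cell_line": line,
                    "mirna_id": m,
                    "n_targets_expressed": res.n_targets_expressed,
                    "n_background": res.n_background,
                    "ks_statistic": res.ks_statistic,
                    "p_value": res.p_value,
                    "signed_shift": res.signed_shift,
                    "direction_consistent": res.direction_consistent,
                    "underpowered": res.underpowered,
                }
            )
            if (
                res.p_value == res.p_value
                and res.p_value < sh["hit_p"]
                and res.direction_consistent
            ):
                hits_per_line[line].add(m)
    frame = pd.DataFrame(rows)
    io.write_tsv(outdir / "shift_results.tsv", frame)
    hits = sorted(set.intersection(*hits_per_line.values())) if shared else []
    _log("shift", f"shared DE miRNAs: {shared}; direction-consistent hits in both lines: {hits}")
    return {"shared_de_mirnas": shared, "shift_hits": hits, "shift_frame": frame, "de_sets": de_sets}


def stage_concordance(config: dict, outdir: Path, quant_state: dict, de_state: dict, shift_state: dict) -> dict:
    """Cross-cell-line DE overlap and LFC concordance."""
    min_count = config["shift"]["min_mirna_count"]
    detected = None
    for line in CELL_LINES:
        mat = quant_state["mirna_matrices"][line]
        ok = {f for f, mean in zip(mat.feature_ids, mat.counts.mean(axis=1)) if mean >= min_count}
        detected = ok if detected is None else (detected & ok)
    universe = sorted(detected)
    sets = {line: shift_state["de_sets"][line] & set(universe) for line in CELL_LINES}
    overlap = shift.concordant_de_overlap(sets[CELL_LINES[0]], sets[CELL_LINES[1]], len(universe))
    shared = shift_state["shared_de_mirnas"]
    pairs = []
    for m in shared:
        l1 = de_state["mirna_de"][CELL_LINES[0]].set_index("feature_id").loc[m, "logFC"]
        l2 = de_state["mirna_de"][CELL_LINES[1]].set_index("feature_id").loc[m, "logFC"]
        pairs.append((float(l1), float(l2)))
    if len(pairs) >= 3:
        r, p = shift.pearson_lfc_concordance(pairs)
    else:
        r, p = float("nan"), float("nan")
    result = {
        "universe_size": len(universe),
        "n_de_line1": len(sets[CELL_LINES[0]]),
        "n_de_line2": len(sets[CELL_LINES[1]]),
        "n_shared": len(shared),
        "overlap_p": overlap.p_value,
        "pearson_r": r,
        "pearson_p": p,
    }
    io.write_tsv(outdir / "concordance.tsv", pd.DataFrame([result]))
    _log("concordance", f"{result}")
    return result


def stage_clinical(config: dict, outdir: Path) -> dict:
    """Biomarker ROC and median-split survival on the clinical table."""
    clinical = io.read_tsv(outdir / "clinical.tsv")
    roc = clinstats.roc_auc(clinical["expression"], clinical["label"])
    surv = clinstats.km_logrank_median_split(clinical)
    result = {
        "auc": roc.auc,
        "auc_ci_low": roc.ci_low,
        "auc_ci_high": roc.ci_high,
        "logrank_chi2": surv.chi2,
        "logrank_p": surv.p_value,
        "hazard_ratio": surv.hazard_ratio,
    }
    io.write_tsv(outdir / "clinical_stats.tsv", pd.DataFrame([result]))
    _log("clinical", f"{result}")
    return result


def load_sim_state(config: dict, outdir: str | Path) -> dict:
    """Rebuild the simulate-stage state from its files, so later stages can
    run standalone (used by the numbered analysis scripts)."""
    outdir = Path(outdir)
    seqs = io.read_fasta(outdir / "genome.fa")
    genome = synthetic.ToyGenome(tuple(seqs), seqs, config["seed"])
    loci = io.read_mirna_gff3(outdir / "mirna_loci.gff3", genome=seqs)
    samples = _sample_names(config["simulate"]["reps_per_group"])
    fastq_paths = {
        (line, s): outdir / f"reads_{line}_{s}.fastq" for line in CELL_LINES for s in samples
    }
    tmap_frame = io.read_tsv(outdir / "target_map.tsv")
    target_map: dict[str, set[str]] = {}
    for m, g in zip(tmap_frame["mirna_id"], tmap_frame["gene_id"]):
        target_map.setdefault(m, set()).add(g)
    truth = io.read_tsv(outdir / "mirna_truth.tsv")
    shift_mirnas = sorted(truth.loc[truth["shift_mirna"], "mirna_id"].unique())
    return {
        "genome": genome,
        "loci": loci,
        "fastq_paths": fastq_paths,
        "samples": samples,
        "shift_mirnas": shift_mirnas,
        "target_map": target_map,
    }


def load_quant_state(outdir: str | Path) -> dict:
    outdir = Path(outdir)
    matrices = {}
    for line in CELL_LINES:
        frame = io.read_tsv(outdir / f"mirna_counts_{line}.tsv", index_col=0)
        groups = ["control" if s.startswith("ctrl") else "knockdown" for s in frame.columns]
        matrices[line] = diffexpr.CountMatrix(
            feature_ids=list(frame.index),
            sample_ids=list(frame.columns),
            counts=frame.to_numpy(),
            groups=groups,
        )
    return {"mirna_matrices": matrices}


def load_de_state(outdir: str | Path) -> dict:
    outdir = Path(outdir)
    return {
        "gene_de": {line: io.read_tsv(outdir / f"gene_de_{line}.tsv") for line in CELL_LINES},
        "mirna_de": {line: io.read_tsv(outdir / f"mirna_de_{line}.tsv") for line in CELL_LINES},
    }


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute all stages in dependency order; returns the run manifest."""
    violations = validate_config(config)
    if violations:
        raise StageError("validate", "; ".join(violations))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": _config_hash(config), "stages": {}}
    state: dict = {}
    stages = [
        ("simulate", lambda: stage_simulate(config, outdir)),
        ("quant", lambda: stage_quant(config, outdir, state["simulate"])),
        ("de", lambda: stage_de(config, outdir, state["simulate"], state["quant"])),
        ("shift", lambda: stage_shift(config, outdir, state["simulate"], state["de"])),
        (
            "concordance",
            lambda: stage_concordance(config, outdir, state["quant"], state["de"], state["shift"]),
        ),
        ("clinical", lambda: stage_clinical(config, outdir)),
    ]
    before = {p.name for p in outdir.iterdir()}
    for name, fn in stages:
        t0 = time.time()
        try:
            state[name] = fn()
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - converted to a machine-readable record
            raise StageError(name, str(exc)) from exc
        new_files = sorted({p.name for p in outdir.iterdir()} - before)
        before |= set(new_files)
        manifest["stages"][name] = {
            "seconds": round(time.time() - t0, 3),
            "outputs": {f: _sha256(outdir / f) for f in new_files},
        }
    summary = {
        "de_summaries": state["de"]["de_summaries"],
        "shared_de_mirnas": state["shift"]["shared_de_mirnas"],
        "shift_hits": state["shift"]["shift_hits"],
        "planted_shift_mirnas": state["simulate"]["shift_mirnas"],
        "concordance": state["concordance"],
        "clinical": state["clinical"],
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    _log("run", "pipeline complete")
    manifest["summary"] = summary
    return manifest
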