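"""Synthetic wound-response dataset with planted ground truth.

Generates a file-backed dataset — gene models on one pseudo-chromosome,
per-mark/time/replicate peak calls, per-gene mark and H3 coverage, and an
RNA-seq count matrix — whose statistical structure matches what the analysis
assumes: NB counts in triplicate over {0,1,3,6,12} h with planted induction
and repression timing, and duplicate ChIP coverage over {0,1,3,6} h with
planted pre-wound mark states (including H3K27me3/active-mark bivalency) and
planted post-wound gains in which H3K9/14ac gains precede H3K4me3 gains in a
designated gene class.

Noise model: H3 depth is Gamma(shape 20, mean 30) per gene/time/replicate;
mark depth is H3 depth x a mark/state ratio x a persistent per-
(gene, mark, replicate) IP-efficiency factor (log-normal, sd 0.15) x a small
per-observation measurement noise (log-normal, sd 0.05).  The persistent
factor cancels in time contrasts, so the null M-value spread is set by the
measurement noise alone (~0.07 log2 units), keeping false differential-
marking calls rare at the |M| > 0.15 threshold while still separating marked
from unmarked genes by a factor ~6 in ratio space.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .expression import ExpressionMatrix
from .genomic import (DEFAULT_MARKS, GeneModel, GenomicInterval, Peak,
                      ValidationError, write_gene_models)

GENE_CLASSES = (
    "rapid_preacetylated",
    "slow_gain_ac_then_me3",
    "prc2_bivalent_induced",
    "prc2_only_silent",
    "repressed_lose_ac",
    "stable",
)

INDUCED_CLASSES = ("rapid_preacetylated", "slow_gain_ac_then_me3",
                   "prc2_bivalent_induced")


@dataclass
class SyntheticConfig:
    n_genes: int = 2000
    rna_times: tuple[float, ...] = (0, 1, 3, 6, 12)
    chip_times: tuple[float, ...] = (0, 1, 3, 6)
    n_rna_reps: int = 3
    n_chip_reps: int = 2
    class_proportions: dict[str, float] = field(default_factory=lambda: {
        "rapid_preacetylated": 0.10,
        "slow_gain_ac_then_me3": 0.15,
        "prc2_bivalent_induced": 0.05,
        "prc2_only_silent": 0.15,
        "repressed_lose_ac": 0.15,
        "stable": 0.40,
    })
    nb_dispersion: float = 0.1
    baseline_mean_log_sd: float = 0.8
    baseline_mean_median: float = 100.0
    library_size_log_sd: float = 0.1
    mark_ratio_marked: float = 2.5
    mark_ratio_unmarked: float = 0.4
    gain_fold: float = 2.0
    peak_dropout_prob: float = 0.05
    ip_efficiency_sd: float = 0.15
    chip_noise_sd: float = 0.05
    #: per-(gene, mark) spread of the enrichment ratio (log-normal sd,
    #: natural log); persistent across times and replicates, so it widens
    #: the A-value range without touching time contrasts
    mark_level_log_sd: float = 0.4
    h3_shape: float = 20.0
    h3_mean: float = 30.0
    gene_length: int = 3000
    gene_gap: int = 2000
    promoter_bp: int = 1000
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"class proportions sum to {total}, not 1")
        unknown = set(self.class_proportions) - set(GENE_CLASSES)
        if unknown:
            raise ValidationError(f"unknown gene classes: {sorted(unknown)}")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be > 0")
        for name in ("peak_dropout_prob",):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        if self.mark_ratio_marked <= self.mark_ratio_unmarked:
            raise ValidationError("marked ratio must exceed unmarked ratio")
        return self


# planted per-class schedules ------------------------------------------------
#
# pre-wound marks, first post-wound gain/loss times (h), and the induction
# time t* driving the expression trajectory.  The slow_gain class carries the
# characteristic acetylation-before-H3K4me3 lag (gain at 1 h vs 3 h, one
# sampling step), mirroring rapidly-reprogrammed loci.

_CLASS_PLAN: dict[str, dict] = {
    "rapid_preacetylated": {
        "t_star": 1.0,
        "pre": {"H3K9_14ac", "H3K27ac", "H3K4me3"},
        "gain": {}, "loss": {},
    },
    "slow_gain_ac_then_me3": {
        "t_star": 3.0,
        # poised H3K27ac only; K9/14ac and K4me3 arrive after wounding
        "pre": {"H3K27ac"},
        "gain": {"H3K9_14ac": 1.0, "H3K4me3": 3.0},
        "loss": {},
    },
    "prc2_bivalent_induced": {
        "t_star": 6.0,
        "pre": {"H3K27me3", "H3K4me3"},
        "gain": {"H3K9_14ac": 3.0},
        "loss": {"H3K27me3": 6.0},
    },
    "prc2_only_silent": {
        "t_star": np.inf,
        "pre": {"H3K27me3"},
        "gain": {}, "loss": {},
    },
    "repressed_lose_ac": {
        "t_star": np.inf,             # repression, not induction
        "repress_time": 3.0,
        "pre": {"H3K9_14ac", "H3K27ac", "H3K4me3", "H3K36me3"},
        "gain": {},
        "loss": {"H3K9_14ac": 3.0, "H3K27ac": 3.0},
    },
    "stable": {
        "t_star": np.inf,
        "pre": None,                  # drawn per gene
        "gain": {}, "loss": {},
    },
}


def plant_truth(config: SyntheticConfig) -> tuple[pd.DataFrame, list[GeneModel]]:
    """Assign gene classes, pre-wound mark states and gain/loss schedules.

    Genes are tiled without overlap on one pseudo-chromosome (alternating
    strands).  Class counts are round(n x proportion) with the remainder
    assigned to "stable"; class labels are shuffled across gene positions.
    Deterministic given the config seed.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    n = config.n_genes

    labels: list[str] = []
    for cls in GENE_CLASSES:
        if cls == "stable":
            continue
        labels += [cls] * round(n * config.class_proportions.get(cls, 0.0))
    labels += ["stable"] * (n - len(labels))
    labels = list(rng.permutation(np.array(labels[:n])))

    genes: list[GeneModel] = []
    pitch = config.gene_length + config.gene_gap
    for i in range(n):
        start = config.gene_gap + i * pitch
        strand = "+" if i % 2 == 0 else "-"
        genes.append(GeneModel(
            f"G{i:05d}",
            GenomicInterval("chrS", start, start + config.gene_length, strand)))

    rows = []
    for i, (g, cls) in enumerate(zip(genes, labels)):
        plan = _CLASS_PLAN[cls]
        if plan["pre"] is None:  # stable: random realistic pre-wound states
            k27 = rng.random() < 0.10
            p_active = 0.15 if k27 else 0.65
            pre = {m for m in ("H3K36me3", "H3K4me3", "H3K9_14ac", "H3K27ac")
                   if rng.random() < p_active}
            if k27:
                pre.add("H3K27me3")
        else:
            pre = set(plan["pre"])
        # planted expression fold: 2^U(1,3) in [2,8] for responsive genes
        fold = float(2.0 ** rng.uniform(1.0, 3.0))
        row = {"gene_id": g.gene_id, "gene_class": cls,
               "t_star": plan["t_star"],
               "repress_time": plan.get("repress_time", np.inf),
               "fold": fold if (cls in INDUCED_CLASSES
                                or cls == "repressed_lose_ac") else 1.0}
        for m in DEFAULT_MARKS:
            row[f"pre_{m}"] = m in pre
            row[f"gain_time_{m}"] = plan["gain"].get(m, np.inf)
            row[f"loss_time_{m}"] = plan["loss"].get(m, np.inf)
        rows.append(row)
    truth = pd.DataFrame(rows).set_index("gene_id")
    return truth, genes


# ---------------------------------------------------------------------------
# expression


def _fold_trajectory(cls: str, t_star: float, repress_time: float, fold: float,
                     times: np.ndarray) -> np.ndarray:
    """Per-class mean multiplier f(t): a pulse peaking at t* for induced
    classes (geometric decay afterwards), a sustained drop for repressed."""
    f = np.ones_like(times, dtype=float)
    if np.isfinite(t_star):
        for j, t in enumerate(times):
            if t >= t_star:
                steps_past = np.sum((times > t_star) & (times <= t))
                f[j] = 1.0 + (fold - 1.0) * 0.5 ** steps_past
    elif np.isfinite(repress_time):
        f[times >= repress_time] = 1.0 / fold
    return f


def simulate_expression(truth: pd.DataFrame, config: SyntheticConfig,
                        inhibitor: bool = False) -> ExpressionMatrix:
    """NB counts, mean = mu_g x f_class(t) x L_r, dispersion phi.

    ``inhibitor=True`` emulates a histone-acetyltransferase-inhibitor arm:
    induction trajectories are flattened (f = 1 for induced classes) while
    repression is untouched.
    """
    if config.nb_dispersion <= 0:
        raise ValidationError("nb_dispersion must be > 0")
    rng = np.random.default_rng([config.seed, 202, int(inhibitor)])
    times = np.asarray(config.rna_times, dtype=float)
    n_samp = len(times) * config.n_rna_reps

    mu = config.baseline_mean_median * np.exp(
        rng.normal(0.0, config.baseline_mean_log_sd, size=len(truth)))
    lib = np.exp(rng.normal(0.0, config.library_size_log_sd, size=n_samp))

    sample_names, meta = [], []
    for t in times:
        for r in range(1, config.n_rna_reps + 1):
            sample_names.append(f"t{t:g}_rep{r}")
            meta.append({"time_h": t, "replicate": r})

    mean = np.empty((len(truth), n_samp))
    for i, (_, row) in enumerate(truth.iterrows()):
        if inhibitor and row["gene_class"] in INDUCED_CLASSES:
            f = np.ones_like(times)
        else:
            f = _fold_trajectory(row["gene_class"], row["t_star"],
                                 row["repress_time"], row["fold"], times)
        mean[i] = mu[i] * np.repeat(f, config.n_rna_reps) * lib

    phi = config.nb_dispersion
    if phi < 1e-8:
        counts = rng.poisson(mean)
    else:
        r = 1.0 / phi
        counts = rng.negative_binomial(r, r / (r + mean))
    cdf = pd.DataFrame(counts, index=truth.index, columns=sample_names)
    samples = pd.DataFrame(meta, index=sample_names)
    return ExpressionMatrix(cdf, samples)


# ---------------------------------------------------------------------------
# ChIP coverage + peaks


def _mark_present(row: pd.Series, mark: str, t: float) -> bool:
    if row[f"pre_{mark}"]:
        return t < row[f"loss_time_{mark}"]
    return t >= row[f"gain_time_{mark}"]


def _mark_ratio(row: pd.Series, mark: str, t: float,
                config: SyntheticConfig) -> float:
    r = (config.mark_ratio_marked if row[f"pre_{mark}"]
         else config.mark_ratio_unmarked)
    if t >= row[f"gain_time_{mark}"]:
        r *= config.gain_fold
    if t >= row[f"loss_time_{mark}"]:
        r /= config.gain_fold
    return r


def simulate_chip(truth: pd.DataFrame, genes: list[GeneModel],
                  config: SyntheticConfig, inhibitor: bool = False
                  ) -> tuple[pd.DataFrame, dict[tuple[str, float, int], list[Peak]]]:
    """Coverage table plus replicate peak sets per mark/time.

    Peaks are emitted (with probability 1 - dropout) inside the gene's
    analysis window wherever the mark is present, with -log10(Q) well above
    the filter; sub-threshold decoy peaks are sprinkled per file.

    ``inhibitor=True`` suppresses acetylation/H3K4me3 gains and halves the
    acetylation ratio of induced-class genes, emulating HAT inhibition.
    """
    rng = np.random.default_rng([config.seed, 303, int(inhibitor)])
    times = np.asarray(config.chip_times, dtype=float)
    reps = range(1, config.n_chip_reps + 1)
    gene_by_id = {g.gene_id: g for g in genes}

    t_arr = truth.copy()
    if inhibitor:
        for m in ("H3K9_14ac", "H3K27ac", "H3K4me3"):
            t_arr[f"gain_time_{m}"] = np.inf

    n = len(t_arr)
    cov_rows: list[dict] = []
    peaks: dict[tuple[str, float, int], list[Peak]] = {
        (m, t, r): [] for m in DEFAULT_MARKS for t in times for r in reps}

    # persistent IP efficiency per (gene, mark, replicate)
    eff = np.exp(rng.normal(0.0, config.ip_efficiency_sd,
                            size=(n, len(DEFAULT_MARKS), config.n_chip_reps)))
    # persistent per-(gene, mark) enrichment-level spread: real marking is
    # graded, not two-valued; cancels exactly in any time contrast
    level_scale = np.exp(rng.normal(0.0, config.mark_level_log_sd,
                                    size=(n, len(DEFAULT_MARKS))))

    for ti, t in enumerate(times):
        h3 = rng.gamma(config.h3_shape,
                       config.h3_mean / config.h3_shape,
                       size=(n, config.n_chip_reps))
        noise = np.exp(rng.normal(0.0, config.chip_noise_sd,
                                  size=(n, len(DEFAULT_MARKS),
                                        config.n_chip_reps)))
        emit = rng.random(size=(n, len(DEFAULT_MARKS), config.n_chip_reps))
        qvals = rng.uniform(5.0, 50.0, size=(n, len(DEFAULT_MARKS),
                                             config.n_chip_reps))
        for i, (gid, row) in enumerate(t_arr.iterrows()):
            body = gene_by_id[gid].body
            for r_i, rep in enumerate(reps):
                cov_rows.append({"gene_id": gid, "track": "H3", "time_h": t,
                                 "replicate": rep, "mean_depth": h3[i, r_i]})
            for m_i, mark in enumerate(DEFAULT_MARKS):
                ratio_damp = 1.0
                if (inhibitor and mark in ("H3K9_14ac", "H3K27ac")
                        and row["gene_class"] in INDUCED_CLASSES):
                    ratio_damp = 0.5
                ratio = (_mark_ratio(row, mark, t, config) * ratio_damp
                         * level_scale[i, m_i])
                present = _mark_present(row, mark, t)
                for r_i, rep in enumerate(reps):
                    depth = (h3[i, r_i] * ratio * eff[i, m_i, r_i]
                             * noise[i, m_i, r_i])
                    cov_rows.append({"gene_id": gid, "track": mark,
                                     "time_h": t, "replicate": rep,
                                     "mean_depth": depth})
                    if present and emit[i, m_i, r_i] >= config.peak_dropout_prob:
                        # interior of the gene body: overlaps this gene's
                        # window only (never book-ends a neighbour's window)
                        iv = GenomicInterval(body.chrom, body.start,
                                             min(body.start + 800, body.end),
                                             ".")
                        peaks[(mark, t, rep)].append(
                            Peak(iv, mark, t, rep, float(qvals[i, m_i, r_i])))

    # sub-threshold decoys: never pass the Q filter
    n_decoy = max(1, n // 20)
    for key in peaks:
        mark, t, rep = key
        picks = rng.integers(0, n, size=n_decoy)
        dq = rng.uniform(0.5, 2.9, size=n_decoy)
        for j, gi in enumerate(picks):
            b = genes[gi].body
            peaks[key].append(Peak(
                GenomicInterval(b.chrom, b.start, b.start + 200, "."),
                mark, t, rep, float(dq[j])))

    cov = pd.DataFrame(cov_rows)
    return cov, peaks


# ---------------------------------------------------------------------------
# file emission


def peak_filename(mark: str, time_h: float, rep: int) -> str:
    return f"peaks_{mark}_t{time_h:g}_rep{rep}.narrowPeak"


def write_peaks(peaks: list[Peak], path: Path) -> None:
    with open(path, "w") as fh:
        for j, p in enumerate(peaks):
            iv = p.interval
            fh.write("\t".join(map(str, [
                iv.chrom, iv.start, iv.end, f"peak{j}", 0, ".",
                f"{p.neg_log10_q:.4f}", -1, f"{p.neg_log10_q:.4f}", -1,
            ])) + "\n")


def write_dataset(config: SyntheticConfig, outdir: str | Path,
                  inhibitor: bool = False) -> dict:
    """Generate and write the complete dataset; returns the manifest dict.

    Emits genes.bed, per-mark/time/replicate narrowPeak files, coverage.tsv,
    counts.tsv, truth.tsv, config.yaml and manifest.json (seed + sha256
    checksums).  Byte-identical across runs with the same config + seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth, genes = plant_truth(config)
    expr = simulate_expression(truth, config, inhibitor=inhibitor)
    cov, peaks = simulate_chip(truth, genes, config, inhibitor=inhibitor)

    write_gene_models(genes, outdir / "genes.bed")
    for (mark, t, rep), plist in sorted(peaks.items()):
        write_peaks(plist, outdir / peak_filename(mark, t, rep))
    cov.to_csv(outdir / "coverage.tsv", sep="\t", index=False,
               float_format="%.6g")
    expr.counts.to_csv(outdir / "counts.tsv", sep="\t")
    expr.samples.to_csv(outdir / "samples.tsv", sep="\t",
                        index_label="sample")
    truth.to_csv(outdir / "truth.tsv", sep="\t", float_format="%.6g")
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump({**asdict(config), "inhibitor": inhibitor}, fh,
                       sort_keys=True)

    manifest = {"seed": config.seed, "inhibitor": inhibitor, "files": {}}
    for f in sorted(outdir.iterdir()):
        if f.name == "manifest.json":
            continue
        manifest["files"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
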