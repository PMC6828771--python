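"""End-to-end orchestration: configuration, dataset loading, the full
pipeline, and the treatment-vs-control contrast mode.

All stages are pure library calls; this module wires them together, logs
per-stage cardinalities, and writes a provenance manifest (config hash,
seed, per-stage row counts) next to the output TSVs.  Re-running with the
same inputs and config reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genomic import (DEFAULT_MARKS, GeneModel, ParseError, ValidationError,
                      read_coverage_table, read_gene_models, read_peaks)
from .expression import (ExpressionMatrix, call_wound_responsive,
                         cluster_induced, expression_profiles,
                         normalize_libraries, run_all_contrasts, test_de,
                         estimate_dispersions, bh_adjust)
from .states import build_state_table, combination_table, marked_gene_sets, \
    write_state_table, enrichment_levels
from .marking import first_gain_times, marking_contrast, ma_transform, \
    rescale_ma, M_THRESHOLD
from .enrich import (cluster_category_enrichment, comark_enrichment,
                     mark_enrichment, representation_factor)
from .dynamics import (classify_ac_category, precedence_counts,
                       rank_loess_timing, temporal_profiles, timing_pca,
                       marking_expression_correlation)

log = logging.getLogger(__name__)

_PEAK_RE = re.compile(r"peaks_(?P<mark>.+)_t(?P<time>[\d.]+)_rep(?P<rep>\d+)"
                      r"\.(narrowPeak|broadPeak)$")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    data_dir: str = "."
    out_dir: str = "results"
    fc_threshold: float = 1.5
    fdr_threshold: float = 0.001
    m_threshold: float = M_THRESHOLD
    min_neg_log10_q: float = 3.0      # peak Q < 0.001
    promoter_bp: int = 1000
    max_distance_bp: int = 0
    k_clusters: int = 8
    n_starts: int = 50
    loess_span: float = 0.3
    seed: int = 0
    marks: tuple[str, ...] = DEFAULT_MARKS
    ac_mark: str = "H3K9_14ac"
    me3_mark: str = "H3K4me3"

    def validate(self) -> "PipelineConfig":
        if not (self.fc_threshold > 1 and 0 < self.fdr_threshold < 1):
            raise ValidationError("fc_threshold > 1 and fdr_threshold in (0,1)")
        if self.m_threshold <= 0 or self.min_neg_log10_q < 0:
            raise ValidationError("thresholds out of documented range")
        if self.k_clusters < 2 or self.promoter_bp < 0:
            raise ValidationError("k_clusters >= 2 and promoter_bp >= 0")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "marks" in raw:
            raw["marks"] = tuple(raw["marks"])
        return cls(**raw).validate()

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str)
            .encode()).hexdigest()[:16]


@dataclass
class Dataset:
    genes: list[GeneModel]
    expression: ExpressionMatrix
    coverage: pd.DataFrame
    peaks: dict[tuple[str, float, int], list]
    chip_times: list[float] = field(default_factory=list)


def load_dataset(data_dir: str | Path, config: PipelineConfig) -> Dataset:
    """Load genes.bed, counts.tsv + samples.tsv, coverage.tsv and every
    peaks_<mark>_t<time>_rep<k>.narrowPeak file from a dataset directory."""
    d = Path(data_dir)
    genes = read_gene_models(d / "genes.bed")
    counts = pd.read_csv(d / "counts.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(d / "samples.tsv", sep="\t", index_col=0)
    expr = ExpressionMatrix(counts, samples)
    coverage = read_coverage_table(d / "coverage.tsv")
    peaks: dict[tuple[str, float, int], list] = {}
    for f in sorted(d.iterdir()):
        m = _PEAK_RE.match(f.name)
        if not m:
            continue
        mark, t, rep = m["mark"], float(m["time"]), int(m["rep"])
        peaks[(mark, t, rep)] = read_peaks(f, mark, t, rep,
                                           config.min_neg_log10_q)
    chip_times = sorted({t for (_, t, _) in peaks})
    return Dataset(genes, expr, coverage, peaks, chip_times)


def run_pipeline(config: PipelineConfig) -> dict:
    """Full analysis over one dataset directory; returns the manifest.

    Stage order: genomic I/O -> expression (TMM, NB exact DE, responsive
    sets, timing clusters) -> chromatin states -> differential marking ->
    enrichment -> dynamics integration.  All outputs land in
    ``config.out_dir``; a failure aborts with the stage name and removes
    partial outputs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {"config": asdict(config), "config_digest": config.digest(),
                      "version": __version__, "stages": {}}

    def emit(name: str, frame: pd.DataFrame, **kw) -> None:
        path = out / name
        frame.to_csv(path, sep="\t", float_format="%.6g", **kw)
        written.append(path)

    try:
        stage = "load"
        data = load_dataset(config.data_dir, config)
        manifest["stages"]["load"] = {
            "n_genes": len(data.genes),
            "n_samples": data.expression.counts.shape[1],
            "n_peak_files": len(data.peaks),
        }
        log.info("load: %d genes, %d RNA samples, %d peak files",
                 len(data.genes), data.expression.counts.shape[1],
                 len(data.peaks))

        stage = "expression"
        factors = normalize_libraries(data.expression)
        de = run_all_contrasts(data.expression, factors)
        induced, repressed = call_wound_responsive(
            de, config.fc_threshold, config.fdr_threshold)
        emit("de_results.tsv", de, index=False)
        (out / "induced_genes.txt").write_text("\n".join(sorted(induced)) + "\n")
        (out / "repressed_genes.txt").write_text(
            "\n".join(sorted(repressed)) + "\n")
        written += [out / "induced_genes.txt", out / "repressed_genes.txt"]
        clusters = cluster_induced(data.expression, factors, induced,
                                   k=config.k_clusters,
                                   n_starts=config.n_starts, seed=config.seed)
        emit("clusters.tsv", clusters.labels.rename_axis("gene_id").to_frame(),
             index=True)
        manifest["stages"]["expression"] = {
            "n_induced": len(induced), "n_repressed": len(repressed),
            "n_contrasts": de["time_h"].nunique(),
        }
        log.info("expression: %d induced, %d repressed", len(induced),
                 len(repressed))

        stage = "chromatin_states"
        state = build_state_table(data.peaks, data.coverage, data.genes,
                                  config.marks, time_h=0.0,
                                  promoter_bp=config.promoter_bp,
                                  max_distance_bp=config.max_distance_bp)
        write_state_table(state, out / "state_table.tsv")
        written.append(out / "state_table.tsv")
        combos = combination_table(state.marked)
        combo_frame = pd.DataFrame(
            [{"combination": "+".join(sorted(c.combination)) or "(none)",
              "count": c.count} for c in combos])
        emit("combinations.tsv", combo_frame, index=False)
        manifest["stages"]["chromatin_states"] = {
            "n_marked_any": int(state.marked.any(axis=1).sum()),
            **{f"n_{m}": int(state.marked[m].sum()) for m in config.marks},
        }

        stage = "differential_marking"
        marked_by_time = {
            t: marked_gene_sets(data.peaks, data.genes, config.marks, t,
                                config.promoter_bp, config.max_distance_bp)
            for t in data.chip_times}
        contrast_times = [t for t in data.chip_times if t != 0.0]
        marking_tables: dict[str, list[pd.DataFrame]] = {}
        all_rows = []
        for mark in config.marks:
            per_time = []
            for t in contrast_times:
                tab = marking_contrast(
                    state.levels, mark, t,
                    marked_by_time[0.0][mark], marked_by_time[t][mark],
                    threshold=config.m_threshold)
                per_time.append(tab)
                all_rows.append(tab.reset_index())
            marking_tables[mark] = per_time
        marking_all = pd.concat(all_rows, ignore_index=True)
        emit("marking_changes.tsv", marking_all, index=False)
        manifest["stages"]["differential_marking"] = {
            "n_calls": int((marking_all["call"] != "none").sum()),
            "n_rows": len(marking_all),
        }

        stage = "enrichment"
        universe = {g.gene_id for g in data.genes}
        mark_enr = mark_enrichment(state.marked, induced, universe)
        emit("mark_enrichment_induced.tsv", mark_enr)
        emit("mark_enrichment_repressed.tsv",
             mark_enrichment(state.marked, repressed, universe))
        emit("comark_enrichment_induced.tsv",
             comark_enrichment(state.marked, induced))
        manifest["stages"]["enrichment"] = {"n_marks": len(mark_enr)}

        stage = "dynamics"
        gain_ac = first_gain_times(marking_tables[config.ac_mark])
        gain_me3 = first_gain_times(marking_tables[config.me3_mark])
        induced_idx = pd.Index(sorted(induced))
        ac_cat = classify_ac_category(
            state.marked.loc[induced_idx, config.ac_mark],
            gain_ac, gain_me3, window_end_h=max(contrast_times))
        emit("ac_categories.tsv", ac_cat, index=True)
        prec = precedence_counts(gain_ac.loc[induced_idx],
                                 gain_me3.loc[induced_idx])
        emit("precedence.tsv", prec.table, index=True)
        emit("precedence_counts.tsv",
             pd.DataFrame({"strict": prec.counts,
                           "inclusive": prec.counts_inclusive}), index=True)
        cce = cluster_category_enrichment(ac_cat["category"], clusters.labels)
        emit("cluster_category_enrichment.tsv", cce, index=False)

        level0 = state.level_matrix(0.0)
        loess_rows, rho_rows = [], []
        for mark in config.marks:
            curve, rho = rank_loess_timing(level0[mark].dropna(),
                                           clusters.labels,
                                           span=config.loess_span)
            curve.insert(0, "mark", mark)
            loess_rows.append(curve)
            rho_rows.append({"mark": mark, "spearman_rho": rho})
        emit("loess_curve.tsv", pd.concat(loess_rows, ignore_index=True),
             index=False)
        emit("loess_rho.tsv", pd.DataFrame(rho_rows), index=False)

        expr_prof = expression_profiles(data.expression, factors,
                                        list(induced_idx))
        pca_vars = level0.loc[induced_idx, list(config.marks)].rank()
        pca_vars["timing"] = clusters.labels.loc[induced_idx].astype(float)
        expr0 = data.expression.counts[
            data.expression.columns_at(0.0)].mean(axis=1)
        pca_vars["expression_0h"] = expr0.loc[induced_idx].rank()
        loadings, var_frac = timing_pca(pca_vars)
        emit("pca_loadings.tsv", loadings, index=True)
        emit("pca_variance.tsv", var_frac.to_frame(), index=True)

        prof, expr_group = temporal_profiles(
            state.levels[state.levels["gene_id"].isin(induced_idx)],
            ac_cat["category"], expr_prof)
        emit("profiles.tsv", prof, index=False)
        if expr_group is not None:
            emit("profiles_expression.tsv", expr_group, index=True)

        corr_rows = []
        de_by_time = {t: de[de["time_h"] == t].set_index("gene_id")["log2FC"]
                      for t in de["time_h"].unique()}
        for mark in config.marks:
            for tab in marking_tables[mark]:
                t = float(tab["time_h"].iloc[0])
                if t not in de_by_time:
                    continue
                r = marking_expression_correlation(tab["M_rescaled"],
                                                   de_by_time[t])
                corr_rows.append({"mark": mark, "time_h": t, "pearson_r": r})
        emit("correlations.tsv", pd.DataFrame(corr_rows), index=False)
        manifest["stages"]["dynamics"] = {
            "precedence_ac_first": prec.ac_first,
            "precedence_me3_first": prec.me3_first,
        }
    except PipelineError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc

    manifest["outputs"] = {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                           for p in sorted(written)}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# treatment-vs-control mode


def _two_group_de(treated: ExpressionMatrix, control: ExpressionMatrix,
                  time_h: float) -> pd.DataFrame:
    """NB exact test of treated vs control at one matched time point."""
    cols_t = treated.columns_at(time_h)
    cols_c = control.columns_at(time_h)
    counts = pd.concat([control.counts[cols_c].add_prefix("ctrl_"),
                        treated.counts[cols_t].add_prefix("trt_")], axis=1)
    samples = pd.DataFrame({
        "time_h": [0.0] * len(cols_c) + [1.0] * len(cols_t),
        "replicate": list(range(1, len(cols_c) + 1))
        + list(range(1, len(cols_t) + 1)),
    }, index=counts.columns)
    m = ExpressionMatrix(counts, samples)
    factors = normalize_libraries(m)
    res = test_de(m, factors, 1.0).table
    res["time_h"] = time_h
    return res


def run_treatment_contrast(config: PipelineConfig, treated_dir: str | Path,
                           control_dir: str | Path) -> dict:
    """Treated-vs-control re-use of the DE and marking machinery.

    Per matched time point: NB exact DE (treated vs control) and MA-rescaled
    marking contrasts; then the triple overlap wound-induced (control arm)
    x treatment-down x acetylation-decreased with representation factors.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    treated = load_dataset(treated_dir, config)
    control = load_dataset(control_dir, config)

    t_rna_t = set(treated.expression.times())
    t_rna_c = set(control.expression.times())
    if t_rna_t != t_rna_c or treated.chip_times != control.chip_times:
        raise ValidationError(
            f"time mismatch between arms: RNA {sorted(t_rna_t ^ t_rna_c)}, "
            f"ChIP {sorted(set(treated.chip_times) ^ set(control.chip_times))}")

    # wound-induced genes from the control arm's own time course
    factors_c = normalize_libraries(control.expression)
    de_c = run_all_contrasts(control.expression, factors_c)
    induced, _ = call_wound_responsive(de_c, config.fc_threshold,
                                       config.fdr_threshold)

    de_tc = pd.concat([_two_group_de(treated.expression, control.expression, t)
                       for t in sorted(t_rna_t)], ignore_index=True)
    de_tc.to_csv(out / "treatment_de.tsv", sep="\t", index=False,
                 float_format="%.6g")
    lfc = np.log2(config.fc_threshold)
    sig = de_tc[de_tc["fdr"] < config.fdr_threshold]
    down = set(sig.loc[sig["log2FC"] < -lfc, "gene_id"])

    # acetylation decrease: treated-vs-control M per matched ChIP time
    levels_t = enrichment_levels(treated.coverage, [config.ac_mark])
    levels_c = enrichment_levels(control.coverage, [config.ac_mark])
    ac_down: set[str] = set()
    for t in treated.chip_times:
        lt = levels_t[levels_t["time_h"] == t].set_index("gene_id")["level"]
        lc = levels_c[levels_c["time_h"] == t].set_index("gene_id")["level"]
        common = lt.index.intersection(lc.index)
        m, a = ma_transform(lt.loc[common].to_numpy(),
                            lc.loc[common].to_numpy())
        m = pd.Series(m, index=common)
        a = pd.Series(a, index=common)
        marked_t = marked_gene_sets(treated.peaks, treated.genes,
                                    [config.ac_mark], t, config.promoter_bp,
                                    config.max_distance_bp)[config.ac_mark]
        marked_c = marked_gene_sets(control.peaks, control.genes,
                                    [config.ac_mark], t, config.promoter_bp,
                                    config.max_distance_bp)[config.ac_mark]
        m_prime, _, _ = rescale_ma(m, a, marked_t & marked_c)
        ac_down |= set(m_prime.index[m_prime < -config.m_threshold])

    universe = {g.gene_id for g in control.genes}
    r1 = representation_factor(len(induced & down), len(down),
                               len(induced), len(universe),
                               "induced_x_treatment_down")
    pair = induced & down
    r2 = representation_factor(len(pair & ac_down), len(pair) or 0,
                               len(ac_down), len(universe),
                               "overlap_x_ac_decreased") if pair else None
    overlap_rows = [{
        "overlap": r.category, "k": r.k, "n": r.n, "K": r.K, "N": r.N,
        "representation_factor": r.representation_factor,
        "p_over": r.p_over,
    } for r in ([r1, r2] if r2 else [r1])]
    pd.DataFrame(overlap_rows).to_csv(out / "treatment_overlap.tsv", sep="\t",
                                      index=False, float_format="%.6g")
    manifest = {
        "config": asdict(config), "config_digest": config.digest(),
        "thresholds": {"fc": config.fc_threshold, "fdr": config.fdr_threshold,
                       "m": config.m_threshold},
        "n_induced": len(induced), "n_treatment_down": len(down),
        "n_ac_decreased": len(ac_down),
        "triple_overlap": len(pair & ac_down),
    }
    with open(out / "treatment_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
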