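"""Expression arithmetic, target calling and end-to-end orchestration.

FPKM[g, s] = counts[g, s] / ((length_bp[g] / 1e3) * (library_size[s] / 1e6));
fold change is the ratio of pooled knockout to pooled wild-type FPKM (FPKM
values floored at 0.1 before ratioing so the ratio stays finite).  A gene is
differentially expressed iff its externally supplied p-value is strictly
below the cutoff.  Down- or up-regulated DE genes become predicted direct
targets when the union of their conserved regions, intersected with the
proximal promoter window (TSS-relative [-1000, +1000)), contains at least
one PWM hit at the calibrated match-score threshold.

Differential-expression testing itself is not reimplemented here (it is an
external tool's job and its p-values are consumed as an input column); the
synthetic path supplies p-values from a two-group comparison of pooled
knockout vs wild-type counts: a z-test on the depth-normalized log count
ratio whose variance carries a replicate-estimated negative-binomial
dispersion term.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import conservation as cons
from . import genome_io as gio
from . import motif as mot
from . import simulate as sim

logger = logging.getLogger("conscan")

FPKM_FLOOR = 0.1
PROXIMAL = (-1000, 1000)


# ---------------------------------------------------------------------------
# expression arithmetic


def compute_fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series | None = None,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    ``counts`` holds one row per gene and one column per sample (a 'length'
    column, if present, supplies gene lengths).  Library sizes default to
    column sums.
    """
    counts = counts.copy()
    if gene_lengths is None:
        if "length" not in counts.columns:
            raise ValueError("gene lengths required ('length' column or argument)")
        gene_lengths = counts.pop("length")
    else:
        counts = counts.drop(columns=["length"], errors="ignore")
        gene_lengths = gene_lengths.reindex(counts.index)
    if (gene_lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    denom = np.outer(gene_lengths / 1e3, library_sizes / 1e6)
    return pd.DataFrame(
        counts.to_numpy(dtype=float) / denom, index=counts.index, columns=counts.columns
    )


@dataclass
class QCReport:
    correlations: dict[str, float]
    upper_bounds: dict[str, float]
    min_r: float
    passed: bool


def replicate_qc(
    counts: pd.DataFrame,
    genotype_map: dict[str, str],
    min_r: float = 0.9,
    force: bool = False,
    log_transform: bool = False,
) -> tuple[QCReport, pd.DataFrame]:
    """Pearson correlation of replicate FPKM, then pooling of counts.

    Replicates of a genotype are pooled (counts summed) only after every
    within-genotype replicate pair correlates above ``min_r`` on per-gene
    FPKM, mirroring the r > 0.9 pooling rule; otherwise the pipeline halts
    unless ``force``.  The gate compares the Fisher-z 95% upper confidence
    bound of each r against ``min_r``: on genome-scale panels the bound is
    indistinguishable from r itself, while on small panels (where the
    Pearson estimate has sampling error of order 1/sqrt(n)) only replicate
    pairs convincingly below the cutoff halt the run.
    ``log_transform`` computes the correlation on
    log1p(FPKM) instead — on small gene panels the linear-scale Pearson is
    dominated by the one or two most-expressed genes and is an unstable QC
    statistic, whereas at genome scale either convention works.
    """
    fpkm = compute_fpkm(counts)
    if log_transform:
        fpkm = np.log1p(fpkm)
    sample_cols = [c for c in counts.columns if c != "length"]
    groups: dict[str, list[str]] = {}
    for s in sample_cols:
        groups.setdefault(genotype_map[s], []).append(s)
    correlations = {}
    upper = {}
    n_genes = fpkm.shape[0]
    half_ci = 1.959964 / np.sqrt(max(n_genes - 3, 1))
    for geno, cols in groups.items():
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                r = float(np.corrcoef(fpkm[cols[i]], fpkm[cols[j]])[0, 1])
                key = f"{cols[i]}~{cols[j]}"
                correlations[key] = r
                upper[key] = float(
                    np.tanh(np.arctanh(min(r, 1.0 - 1e-12)) + half_ci)
                )
    passed = all(u > min_r for u in upper.values())
    report = QCReport(correlations, upper, min_r, passed)
    if not passed and not force:
        raise RuntimeError(
            f"replicate QC failed (min r = {min(correlations.values()):.3f}, "
            f"upper bound {min(upper.values()):.3f} <= {min_r}); "
            "rerun with force to pool anyway"
        )
    pooled = pd.DataFrame(
        {geno: counts[cols].sum(axis=1) for geno, cols in groups.items()},
        index=counts.index,
    )
    if "length" in counts.columns:
        pooled.insert(0, "length", counts["length"])
    return report, pooled


def _size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (robust to a down-regulated subset)."""
    mat = counts.drop(columns=["length"], errors="ignore").astype(float)
    logref = np.log(mat.replace(0, np.nan)).mean(axis=1)
    usable = np.isfinite(logref)
    if not usable.any():
        raise ValueError("no gene expressed in every sample; cannot normalize")
    ratios = np.log(mat.loc[usable]).sub(logref[usable], axis=0)
    return np.exp(ratios.median(axis=0))


def estimate_dispersion(
    counts: pd.DataFrame, genotype_map: dict[str, str], min_mean: float = 10.0
) -> float:
    """Global NB dispersion by method of moments on within-genotype replicates.

    For each genotype's depth-normalized replicate counts, per-gene
    ``alpha_g = (s^2 - m) / m^2``; the estimate is the mean over genes with
    mean >= ``min_mean``, clipped at 0.  With few replicates each per-gene
    value is very noisy (s^2 has one degree of freedom at n=2) but unbiased,
    so averaging over genes is stable where a median would be biased low by
    the skew of chi-square with one degree of freedom.
    """
    mat = counts.drop(columns=["length"], errors="ignore").astype(float)
    norm = mat / _size_factors(mat)
    alphas = []
    groups: dict[str, list[str]] = {}
    for s, geno in genotype_map.items():
        groups.setdefault(geno, []).append(s)
    for cols in groups.values():
        if len(cols) < 2:
            continue
        sub = norm[cols]
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        ok = m >= min_mean
        alphas.append(((s2[ok] - m[ok]) / m[ok] ** 2).to_numpy())
    if not alphas:
        return 0.0
    pooled = np.concatenate(alphas)
    return float(max(0.0, np.mean(pooled)))


def count_de_pvalues(
    pooled: pd.DataFrame,
    dispersion: float = 0.0,
    n_replicates: int = 2,
    ko: str = "KO",
    wt: str = "WT",
) -> pd.Series:
    """Two-group comparison of pooled KO vs WT counts under NB noise.

    The per-gene statistic is the log ratio of depth-normalized pooled
    counts (median-of-ratios size factors; half-count continuity
    correction), with variance ``1/k + 1/w + dispersion * 2/n_replicates``
    — the delta-method variance of a log negative-binomial total — and a
    two-sided normal p-value.  With ``dispersion=0`` this reduces to the
    Poisson rate-ratio z-test.
    """
    mat = pooled[[wt, ko]].astype(float)
    sf = _size_factors(mat)
    k = mat[ko].to_numpy() + 0.5
    w = mat[wt].to_numpy() + 0.5
    log_ratio = np.log(k / float(sf[ko])) - np.log(w / float(sf[wt]))
    var = 1.0 / k + 1.0 / w + dispersion * 2.0 / n_replicates
    z = log_ratio / np.sqrt(var)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return pd.Series(pvals, index=pooled.index, name="de_pvalue")


def expression_table(
    pooled: pd.DataFrame,
    pvalues: pd.Series | None = None,
    ko: str = "KO",
    wt: str = "WT",
) -> pd.DataFrame:
    """Per-gene pooled FPKM, KO/WT fold change and direction.

    FPKM is floored at 0.1 before ratioing so fold changes stay finite for
    silent genes; direction is 'up' for fold change > 1, 'down' for < 1.
    """
    fpkm = compute_fpkm(pooled)
    floored = fpkm.clip(lower=FPKM_FLOOR)
    fc = floored[ko] / floored[wt]
    table = pd.DataFrame(
        {
            "length": pooled["length"],
            f"fpkm_{wt}": fpkm[wt],
            f"fpkm_{ko}": fpkm[ko],
            "fold_change": fc,
            "direction": np.where(fc > 1, "up", np.where(fc < 1, "down", "unchanged")),
        }
    )
    if pvalues is not None:
        table["de_pvalue"] = pvalues.reindex(table.index)
    return table


def classify_de(
    expression: pd.DataFrame, p_cutoff: float = 0.05
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Partition genes into up-/down-regulated DE lists (strict p < cutoff).

    Genes with fold change exactly 1 yet p below the cutoff are flagged
    inconsistent and left out of both lists.
    """
    if "de_pvalue" not in expression.columns:
        raise ValueError("expression table lacks a de_pvalue column")
    table = expression.copy()
    is_de = table["de_pvalue"] < p_cutoff
    table["is_de"] = is_de
    table["inconsistent"] = is_de & (table["direction"] == "unchanged")
    up = sorted(table.index[is_de & (table["direction"] == "up")])
    down = sorted(table.index[is_de & (table["direction"] == "down")])
    return up, down, table


# ---------------------------------------------------------------------------
# target calling


@dataclass
class TargetCall:
    """Per-gene verdict: DE status joined with conserved-proximal motif hits."""

    gene_id: str
    is_de: bool
    direction: str
    n_hits: int
    hits: list[mot.MotifHit] = field(default_factory=list)
    tss_offsets: list[int] = field(default_factory=list)
    status: str = "ok"  # ok | no_ortholog | missing_annotation

    @property
    def is_predicted_target(self) -> bool:
        return self.n_hits >= 1


def _intersect(lo1, hi1, lo2, hi2):
    lo, hi = max(lo1, lo2), min(hi1, hi2)
    return (lo, hi) if lo < hi else None


def call_targets(
    de_genes: list[str],
    gene_models: dict[str, gio.GeneModel],
    promoters: dict[str, tuple[str, gio.PromoterWindow]],
    regions: dict[str, list[cons.ConservedRegion]],
    pwm: mot.PWM,
    threshold: float,
    directions: dict[str, str] | None = None,
    proximal: tuple[int, int] = PROXIMAL,
    use_conservation: bool = True,
) -> tuple[list[TargetCall], list[str]]:
    """Scan DE genes' conserved & proximal promoter sequence for PWM hits.

    For each DE gene the scan space is the union of its conserved regions
    intersected with the proximal window (both in promoter offsets); only
    windows fully inside that space can hit.  Genes without an ortholog
    (hence no conserved regions) get ``status='no_ortholog'`` and zero hits;
    genes absent from the annotation go to the exclusions list.  With
    ``use_conservation=False`` the raw proximal window is scanned instead.
    """
    calls: list[TargetCall] = []
    excluded: list[str] = []
    directions = directions or {}
    for g in de_genes:
        if g not in gene_models or g not in promoters:
            excluded.append(g)
            continue
        seq, win = promoters[g]
        prox_lo = win.upstream_bp + proximal[0]
        prox_hi = win.upstream_bp + proximal[1]
        if use_conservation:
            gene_regions = regions.get(g)
            if gene_regions is None:
                calls.append(
                    TargetCall(g, True, directions.get(g, "?"), 0, status="no_ortholog")
                )
                continue
            spans = [
                iv
                for r in gene_regions
                if (iv := _intersect(r.start, r.end, prox_lo, prox_hi))
            ]
        else:
            spans = [(max(0, prox_lo), min(len(seq), prox_hi))]
        hits: list[mot.MotifHit] = []
        offsets: list[int] = []
        for lo, hi in spans:
            if hi - lo < pwm.length:
                continue
            for h in mot.scan(pwm, seq[lo:hi], threshold, seq_id=g):
                off = lo + h.offset
                hits.append(
                    mot.MotifHit(g, off, h.strand, h.match_score, h.site)
                )
                offsets.append(off - win.upstream_bp)
        calls.append(
            TargetCall(g, True, directions.get(g, "?"), len(hits), hits, offsets)
        )
    return calls, excluded


def summarize(
    calls: list[TargetCall],
    up: list[str],
    down: list[str],
    n_detected: int,
    calibration: mot.CalibrationResult | None = None,
) -> tuple[pd.DataFrame, str]:
    """Run report: DE and predicted-target counts plus calibration settings."""
    predicted = sorted(c.gene_id for c in calls if c.is_predicted_target)
    pred_up = [g for g in predicted if g in set(up)]
    pred_down = [g for g in predicted if g in set(down)]
    rows = [
        ("genes_detected", n_detected),
        ("de_up", len(up)),
        ("de_down", len(down)),
        ("de_total", len(up) + len(down)),
        ("predicted_targets", len(predicted)),
        ("predicted_targets_up", len(pred_up)),
        ("predicted_targets_down", len(pred_down)),
    ]
    table = pd.DataFrame(rows, columns=["metric", "value"]).set_index("metric")
    lines = ["conscan run report", "=" * 30]
    lines += [f"{k:>24}: {v}" for k, v in rows]
    if calibration is not None:
        lines += [
            f"{'score threshold':>24}: {calibration.threshold:.6f}",
            f"{'allowed rate /10kbp':>24}: {calibration.allowed_rate:g}",
            f"{'achieved rate /10kbp':>24}: {calibration.achieved_rate:.4f}",
            f"{'negative set bp':>24}: {calibration.total_bp}",
        ]
    lines.append("predicted targets: " + (", ".join(predicted) or "(none)"))
    return table, "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# end-to-end orchestration


@dataclass
class PipelineResult:
    expression: pd.DataFrame
    up: list[str]
    down: list[str]
    calls: list[TargetCall]
    excluded: list[str]
    calibration: mot.CalibrationResult
    regions: dict[str, list[cons.ConservedRegion]]
    qc: QCReport
    truth: sim.TruthTable | None
    report_text: str
    summary: pd.DataFrame

    @property
    def predicted_targets(self) -> list[str]:
        return sorted(c.gene_id for c in self.calls if c.is_predicted_target)

    def precision_recall(self) -> tuple[float, float]:
        """Predicted-target precision/recall against the simulation truth."""
        if self.truth is None:
            raise ValueError("no ground truth attached to this run")
        truth_pos = {g for g, t in self.truth.is_target.items() if t}
        pred = set(self.predicted_targets)
        tp = len(pred & truth_pos)
        precision = tp / len(pred) if pred else 1.0
        recall = tp / len(truth_pos) if truth_pos else 1.0
        return precision, recall


DEFAULT_CONFIG: dict = {
    "min_identity": 80.0,
    "window_bp": 100,
    "step_bp": 10,
    "min_region_bp": 50,
    "allowed_rate": 3.0,
    "p_cutoff": 0.05,
    "align_band": 100,
    "use_conservation": True,
    "qc_log": True,
    "qc_min_r": 0.9,
}


def run_synthetic_pipeline(
    sim_config: sim.SimulationConfig,
    pwm: mot.PWM | None = None,
    params: dict | None = None,
) -> PipelineResult:
    """simulate -> conserve -> calibrate -> fpkm/QC -> classify -> call -> report."""
    p = dict(DEFAULT_CONFIG)
    p.update(params or {})
    pwm = pwm or sim.xbox_demo_pwm()
    t0 = time.perf_counter()

    pair = sim.simulate_genome_pair(sim_config, pwm)
    neg = sim.simulate_negative_control(sim_config)
    lengths = {g.gene_id: g.length_bp for g in pair.genes_a}
    counts = sim.simulate_counts(sim_config, pair.truth, lengths)
    logger.info("simulated dataset in %.2fs", time.perf_counter() - t0)

    t0 = time.perf_counter()
    calibration = mot.calibrate_threshold(pwm, neg, allowed_rate=p["allowed_rate"])
    logger.info(
        "calibrated threshold %.4f (achieved %.3f /10kbp) in %.2fs",
        calibration.threshold, calibration.achieved_rate, time.perf_counter() - t0,
    )

    t0 = time.perf_counter()
    models_b = {g.gene_id: g for g in pair.genes_b}
    up_bp = sim_config.promoter_upstream_bp
    down_bp = sim_config.promoter_downstream_bp
    promoters: dict[str, tuple[str, gio.PromoterWindow]] = {}
    regions: dict[str, list[cons.ConservedRegion]] = {}
    for gene in pair.genes_a:
        seq_a, win = gio.extract_promoter(pair.genome_a, gene, up_bp, down_bp)
        promoters[gene.gene_id] = (seq_a, win)
        if gene.ortholog_id is None or gene.ortholog_id not in models_b:
            continue
        seq_b, _ = gio.extract_promoter(
            pair.genome_b, models_b[gene.ortholog_id], up_bp, down_bp
        )
        aln = cons.align_promoters(
            seq_a, seq_b, band=p["align_band"], gene_id=gene.gene_id
        )
        regions[gene.gene_id] = cons.extract_conserved_regions(
            aln,
            min_identity=p["min_identity"],
            window_bp=p["window_bp"],
            step_bp=p["step_bp"],
            min_region_bp=p["min_region_bp"],
        )
    logger.info("conservation filtering in %.2fs", time.perf_counter() - t0)

    genotype_map = {c: ("KO" if c.startswith("KO") else "WT") for c in counts.columns if c != "length"}
    qc, pooled = replicate_qc(
        counts, genotype_map, min_r=p["qc_min_r"], log_transform=p["qc_log"]
    )
    alpha = estimate_dispersion(counts, genotype_map)
    pvals = count_de_pvalues(
        pooled, dispersion=alpha, n_replicates=sim_config.n_replicates
    )
    expression = expression_table(pooled, pvals)
    up, down, expression = classify_de(expression, p_cutoff=p["p_cutoff"])

    models_a = {g.gene_id: g for g in pair.genes_a}
    directions = expression["direction"].to_dict()
    calls, excluded = call_targets(
        sorted(set(up) | set(down)),
        models_a,
        promoters,
        regions,
        pwm,
        calibration.threshold,
        directions=directions,
        use_conservation=p["use_conservation"],
    )
    summary, text = summarize(calls, up, down, len(expression), calibration)
    return PipelineResult(
        expression, up, down, calls, excluded, calibration, regions, qc,
        pair.truth, text, summary,
    )


def write_results(result: PipelineResult, outdir) -> dict[str, Path]:
    """Write targets, exclusions, expression, summary and report files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "targets": out / "targets.tsv",
        "exclusions": out / "exclusions.tsv",
        "expression": out / "expression.tsv",
        "summary": out / "summary.tsv",
        "report": out / "report.txt",
        "calibration": out / "calibration.json",
    }
    rows = []
    for c in result.calls:
        rows.append(
            {
                "gene": c.gene_id,
                "direction": c.direction,
                "status": c.status,
                "n_hits": c.n_hits,
                "is_predicted_target": int(c.is_predicted_target),
                "hit_offsets_tss": ";".join(str(o) for o in c.tss_offsets),
                "hit_strands": ";".join(h.strand for h in c.hits),
                "hit_scores": ";".join(f"{h.match_score:.6f}" for h in c.hits),
                "hit_sites": ";".join(h.site for h in c.hits),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "gene", "direction", "status", "n_hits", "is_predicted_target",
            "hit_offsets_tss", "hit_strands", "hit_scores", "hit_sites",
        ],
    ).to_csv(paths["targets"], sep="\t", index=False)
    pd.DataFrame({"gene": result.excluded}).to_csv(
        paths["exclusions"], sep="\t", index=False
    )
    result.expression.to_csv(paths["expression"], sep="\t")
    result.summary.to_csv(paths["summary"], sep="\t")
    paths["report"].write_text(result.report_text)
    cal = result.calibration
    paths["calibration"].write_text(
        json.dumps(
            {
                "threshold": cal.threshold,
                "allowed_rate": cal.allowed_rate,
                "achieved_rate": cal.achieved_rate,
                "total_bp": cal.total_bp,
                "n_hits": cal.n_hits,
            },
            indent=2,
        )
        + "\n"
    )
    return paths


def load_run_config(path) -> tuple[sim.SimulationConfig, dict]:
    """Read a YAML run config: simulation keys plus pipeline parameter keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_keys = {f.name for f in sim.SimulationConfig.__dataclass_fields__.values()}
    sim_kwargs = {k: v for k, v in raw.items() if k in sim_keys}
    if "background_base_composition" in sim_kwargs:
        sim_kwargs["background_base_composition"] = tuple(
            sim_kwargs["background_base_composition"]
        )
    params = {k: v for k, v in raw.items() if k in DEFAULT_CONFIG}
    unknown = set(raw) - sim_keys - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return sim.SimulationConfig(**sim_kwargs), params
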