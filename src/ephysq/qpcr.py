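"""Relative qPCR quantification with multi-reference normalization.

Implements the E^-dCT workflow for CT tables with triplicate wells: per
(sample, gene) CT means, relative quantities ``RQ = E^(CTbar_g - CT_sg)``
against the all-sample mean CT of each gene, a per-sample normalization
factor that is the geometric mean of the RQs of the reference
(housekeeping) genes, and a final rescaling so the control-group mean is 1
within each gene x stratum (Zeitgeber time / hemisphere) cell.  Group
comparisons are per-stratum two-sample t-tests with multiple-testing
correction across the gene x stratum family.

The synthetic panel generator emulates the circadian design of the kainic-
acid experiments: two groups (control vs KA-treated), four Zeitgeber times,
per-gene cosinor baselines, programmed treatment fold changes, and Gaussian
well-to-well CT noise, with Hprt1 and Eef1a1 as untouched reference genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .summary_stats import adjust_pvalues

logger = logging.getLogger(__name__)

__all__ = [
    "CtPanel",
    "ExpressionTable",
    "GeneSpec",
    "PanelDesign",
    "default_panel_design",
    "aggregate_triplicates",
    "relative_expression",
    "compare_groups",
    "simulate_ct_panel",
]

_CT_COLUMNS = ["sample_id", "group", "zt", "hemisphere", "gene", "well", "ct"]


@dataclass(frozen=True)
class CtPanel:
    """Long-format CT table plus reference-gene designation and efficiency.

    ``data`` columns: sample_id, group ('control'/'treated'), zt (hours or
    NaN), hemisphere ('ipsi'/'contra' or NaN), gene, well, ct.  ``efficiency``
    is the per-cycle amplification factor, a scalar for all genes or a
    per-gene mapping (default 2.0, the ideal-doubling reading of 2^-dCT).
    """

    data: pd.DataFrame
    reference_genes: frozenset[str]
    efficiency: float | dict = 2.0

    def __post_init__(self) -> None:
        missing = [c for c in _CT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"CT table missing columns: {missing}")
        ct = self.data["ct"]
        if not np.all(np.isfinite(ct)):
            raise ValueError("CT values must be finite")
        if not self.reference_genes:
            raise ValueError("at least one reference gene is required")
        genes = set(self.data["gene"])
        absent = set(self.reference_genes) - genes
        if absent:
            raise ValueError(f"reference genes absent from table: {sorted(absent)}")
        reps = self.data.groupby(["sample_id", "gene"], dropna=False).size()
        if reps.max() > 3:
            raise ValueError("more than 3 replicate wells for a sample x gene")
        for g in genes:
            if not 1.0 < self.gene_efficiency(g) <= 2.0:
                raise ValueError(f"efficiency for {g} must lie in (1, 2]")

    def gene_efficiency(self, gene: str) -> float:
        if isinstance(self.efficiency, dict):
            return float(self.efficiency.get(gene, 2.0))
        return float(self.efficiency)


@dataclass(frozen=True)
class ExpressionTable:
    """Normalized relative expression; control-group mean is 1 per
    gene x stratum."""

    data: pd.DataFrame  # sample_id, group, zt, hemisphere, gene, normalized_rel_expr
    reference_genes: frozenset[str]


def aggregate_triplicates(
    panel: CtPanel, sd_flag_cycles: float = 0.5
) -> pd.DataFrame:
    """Mean CT per (sample, gene) across available replicate wells.

    Returns columns sample_id, group, zt, hemisphere, gene, ct_mean,
    n_replicates, ct_sd, high_variance.  Records whose replicate SD exceeds
    ``sd_flag_cycles`` are flagged (not removed) for QC review.
    """
    g = panel.data.groupby(
        ["sample_id", "group", "zt", "hemisphere", "gene"], dropna=False
    )["ct"]
    out = g.agg(ct_mean="mean", n_replicates="size", ct_sd="std").reset_index()
    out["ct_sd"] = out["ct_sd"].fillna(0.0)
    out["high_variance"] = out["ct_sd"] > sd_flag_cycles
    n_flagged = int(out["high_variance"].sum())
    if n_flagged:
        logger.info("aggregate_triplicates: %d high-variance records flagged",
                    n_flagged)
    return out


def _strata_key(df: pd.DataFrame) -> pd.Series:
    zt = df["zt"].astype(object).where(df["zt"].notna(), "-")
    hemi = df["hemisphere"].astype(object).where(df["hemisphere"].notna(), "-")
    return zt.astype(str) + "|" + hemi.astype(str)


def relative_expression(panel: CtPanel, rescale: bool = True) -> ExpressionTable:
    """E^-dCT quantification with geometric-mean reference normalization.

    Per gene g and sample s: ``RQ = E_g^(CTbar_g - CT_sg)`` with CTbar_g the
    mean aggregated CT of gene g over all samples; the normalization factor
    ``NF_s`` is the geometric mean of the reference-gene RQs of sample s;
    normalized expression ``RQ / NF_s`` is finally rescaled so the
    control-group mean is exactly 1 within each gene x (zt, hemisphere)
    stratum.  ``rescale=False`` skips that anchoring — use it to inspect
    across-stratum structure such as circadian profiles, which the per-
    stratum anchoring deliberately removes.
    """
    agg = aggregate_triplicates(panel)

    # every sample must carry every reference gene
    by_sample = agg.groupby("sample_id")["gene"].agg(set)
    for sid, genes in by_sample.items():
        lacking = set(panel.reference_genes) - genes
        if lacking:
            raise ValueError(
                f"sample {sid!r} is missing reference gene(s) {sorted(lacking)}"
            )

    agg = agg.copy()
    ct_bar = agg.groupby("gene")["ct_mean"].transform("mean")
    eff = agg["gene"].map(panel.gene_efficiency).astype(float)
    agg["rq"] = eff ** (ct_bar - agg["ct_mean"])

    ref = agg[agg["gene"].isin(panel.reference_genes)]
    nf = ref.groupby("sample_id")["rq"].apply(lambda v: float(stats.gmean(v)))
    agg["nf"] = agg["sample_id"].map(nf)
    agg["normalized_rel_expr"] = agg["rq"] / agg["nf"]

    cols = ["sample_id", "group", "zt", "hemisphere", "gene",
            "normalized_rel_expr"]
    if not rescale:
        return ExpressionTable(data=agg[cols].reset_index(drop=True),
                               reference_genes=panel.reference_genes)

    # rescale: control mean -> 1 within each gene x stratum
    agg["_stratum"] = _strata_key(agg)
    out_parts = []
    for (gene, stratum), sub in agg.groupby(["gene", "_stratum"], sort=False):
        ctrl = sub.loc[sub["group"] == "control", "normalized_rel_expr"]
        if ctrl.empty:
            raise ValueError(
                f"no control samples for gene {gene!r}, stratum {stratum!r}: "
                "cannot anchor the control mean at 1"
            )
        sub = sub.copy()
        sub["normalized_rel_expr"] = sub["normalized_rel_expr"] / ctrl.mean()
        out_parts.append(sub)
    out = pd.concat(out_parts, ignore_index=True)
    return ExpressionTable(data=out[cols], reference_genes=panel.reference_genes)


def compare_groups(
    expr: ExpressionTable,
    stratify_by: tuple[str, ...] = ("zt",),
    method: str = "bh",
    variant: str = "welch",
) -> pd.DataFrame:
    """Treated-vs-control t-test per gene x stratum, with adjustment.

    Reference genes are excluded from the tested family (they define the
    normalization).  Strata with fewer than 2 samples per group are skipped
    with a log entry.  ``p_adjusted`` is computed across all tested
    gene x stratum cells with :func:`ephysq.summary_stats.adjust_pvalues`.
    """
    for col in stratify_by:
        if col not in ("zt", "hemisphere"):
            raise ValueError("stratify_by entries must be 'zt' or 'hemisphere'")
    df = expr.data[~expr.data["gene"].isin(expr.reference_genes)].copy()
    keys = ["gene", *stratify_by]
    rows = []
    for key, sub in df.groupby(keys, dropna=False, sort=False):
        key = key if isinstance(key, tuple) else (key,)
        ctrl = sub.loc[sub["group"] == "control", "normalized_rel_expr"].to_numpy()
        trt = sub.loc[sub["group"] == "treated", "normalized_rel_expr"].to_numpy()
        if ctrl.size < 2 or trt.size < 2:
            logger.info("compare_groups: skipping %s (n_control=%d, n_treated=%d)",
                        key, ctrl.size, trt.size)
            continue
        if np.var(ctrl) == 0 and np.var(trt) == 0:
            # degenerate noise-free panels: identical -> no evidence,
            # different constants -> unambiguous difference
            same = ctrl.mean() == trt.mean()
            t = 0.0 if same else np.inf * np.sign(trt.mean() - ctrl.mean())
            p = 1.0 if same else 0.0
        else:
            t, p = stats.ttest_ind(trt, ctrl, equal_var=(variant == "pooled"))
        rows.append({
            "gene": key[0],
            **dict(zip(stratify_by, key[1:])),
            "mean_ratio": float(trt.mean() / ctrl.mean()),
            "t": float(t),
            "p": float(p),
            "n_control": int(ctrl.size),
            "n_treated": int(trt.size),
        })
    res = pd.DataFrame(rows)
    if not res.empty:
        res["p_adjusted"] = adjust_pvalues(res["p"].to_numpy(), method=method)
    return res


@dataclass(frozen=True)
class GeneSpec:
    """Design of one gene: baseline CT, cosinor rhythm, treatment effect.

    ``treated_fold_change`` is the programmed expression ratio of the
    treated group (0.25 = 4-fold knockdown); it maps to a CT shift of
    ``-log_E(fold_change)`` cycles.  ``amplitude_cycles`` is the cosinor
    amplitude in CT cycles, peaking (lowest CT) at ``peak_zt`` hours.
    """

    baseline_ct: float
    amplitude_cycles: float = 0.0
    peak_zt: float = 0.0
    treated_fold_change: float = 1.0

    def __post_init__(self) -> None:
        if self.treated_fold_change <= 0:
            raise ValueError("treated_fold_change must be positive")
        if self.amplitude_cycles < 0:
            raise ValueError("amplitude_cycles must be >= 0")


@dataclass(frozen=True)
class PanelDesign:
    """Factorial design of a synthetic CT panel."""

    genes: dict[str, GeneSpec]
    reference_genes: tuple[str, ...] = ("Hprt1", "Eef1a1")
    zts: tuple = (0, 6, 12, 18)
    groups: tuple[str, ...] = ("control", "treated")
    hemispheres: tuple = (None,)
    n_per_group: int = 5
    n_replicates: int = 3
    noise_sd_cycles: float = 0.25
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("design lists no genes")
        missing = [g for g in self.reference_genes if g not in self.genes]
        if missing:
            raise ValueError(f"reference genes not designed: {missing}")
        for g in self.reference_genes:
            spec = self.genes[g]
            if spec.treated_fold_change != 1.0:
                raise ValueError(
                    f"reference gene {g} must have treated_fold_change == 1"
                )
        if self.n_per_group < 1 or not 1 <= self.n_replicates <= 3:
            raise ValueError("invalid n_per_group or n_replicates")
        if self.noise_sd_cycles < 0:
            raise ValueError("noise_sd_cycles must be >= 0")
        if not 1.0 < self.efficiency <= 2.0:
            raise ValueError("efficiency must lie in (1, 2]")


def default_panel_design(
    n_per_group: int = 5, noise_sd_cycles: float = 0.25
) -> PanelDesign:
    """Clock-output panel emulating the circadian knockdown experiments.

    PAR bZIP activators (Hlf, Dbp, Tef) are programmed down in the treated
    group (Hlf 4-fold, Dbp and Tef 2-fold), the repressor E4bp4 up 2-fold;
    low cosinor amplitudes reflect the weak diurnal oscillation of these
    factors in brain tissue.  References Hprt1/Eef1a1 are flat and
    unaffected.
    """
    genes = {
        "Hlf": GeneSpec(24.0, amplitude_cycles=0.3, peak_zt=12,
                        treated_fold_change=0.25),
        "Dbp": GeneSpec(23.0, amplitude_cycles=0.5, peak_zt=10,
                        treated_fold_change=0.5),
        "Tef": GeneSpec(24.5, amplitude_cycles=0.3, peak_zt=12,
                        treated_fold_change=0.5),
        "E4bp4": GeneSpec(25.0, amplitude_cycles=0.3, peak_zt=0,
                          treated_fold_change=2.0),
        "Hprt1": GeneSpec(22.0),
        "Eef1a1": GeneSpec(18.0),
    }
    return PanelDesign(genes=genes, n_per_group=n_per_group,
                       noise_sd_cycles=noise_sd_cycles)


def simulate_ct_panel(design: PanelDesign, seed: int = 0) -> CtPanel:
    """Generate a CT panel from a factorial design; deterministic per seed.

    ``CT = baseline - amplitude*cos(2*pi*(zt - peak)/24) - log_E(fold) [if
    treated] + Normal(0, noise_sd)`` independently per replicate well.
    """
    rng = np.random.default_rng(seed)
    log_e = math.log(design.efficiency)
    rows = []
    for hemi in design.hemispheres:
        for zt in design.zts:
            for group in design.groups:
                for i in range(design.n_per_group):
                    zt_tag = "na" if zt is None else str(zt)
                    hemi_tag = "" if hemi is None else f"_{hemi}"
                    sid = f"{group}_zt{zt_tag}{hemi_tag}_{i + 1}"
                    for gene, spec in design.genes.items():
                        mu = spec.baseline_ct
                        if zt is not None and spec.amplitude_cycles:
                            mu -= spec.amplitude_cycles * math.cos(
                                2 * math.pi * (zt - spec.peak_zt) / 24.0
                            )
                        if group == "treated":
                            mu -= math.log(spec.treated_fold_change) / log_e
                        for well in range(design.n_replicates):
                            ct = mu
                            if design.noise_sd_cycles > 0:
                                ct += rng.normal(0.0, design.noise_sd_cycles)
                            rows.append((sid, group, zt, hemi, gene,
                                         f"w{well + 1}", ct))
    data = pd.DataFrame(rows, columns=_CT_COLUMNS)
    return CtPanel(data=data,
                   reference_genes=frozenset(design.reference_genes),
                   efficiency=design.efficiency)
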