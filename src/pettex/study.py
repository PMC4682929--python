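"""Statistical characterization of texture indices.

Two questions drive the analysis:

1. How strongly does each texture index track the VOI volume (confound) and
   the VOI SUVmax (signal), summarized by Spearman rank correlations; and
2. can the indices separate tissue types (tumor vs healthy reference, paired
   per patient) and cancer subtypes (adenocarcinoma-like vs squamous-like,
   unpaired), tested with Wilcoxon signed-rank / rank-sum tests.

The phantom experiment draws spheres of growing diameter in a simulated
uniform phantom and profiles each index against the sphere voxel count; an
index that "plateaus" (stops changing beyond some volume) is usable above
that volume, one that keeps growing (RLNU) mostly measures volume.  The
cohort experiment runs the full pipeline on the synthetic cohort: simulate,
filter, segment, relocate into the liver, extract indices under relative and
absolute resampling, and tabulate comparisons shaped like the study tables.

Raw p-values are reported (no correction), with a Holm-adjusted column
emitted alongside since the number of simultaneous tests is non-trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .resampling import AR15, AR20, AR25, RR_SPEC, ResamplingSpec
from .synthetic import (
    CohortLedger,
    CohortSpec,
    PhantomSpec,
    apply_exclusions,
    default_sphere_centers,
    liver_center,
    simulate_cohort,
    simulate_phantom,
)
from .texture import SEVEN_TI, extract_ti
from .voi import (
    SegmentationError,
    adaptive_threshold_segment,
    metabolic_volume,
    relocate_voi,
    sphere_voi,
)
from .volumes import VolumeGrid

#: table rows in study order; suvmax/mv map to the feature columns below
METRIC_COLUMNS = {ti: ti for ti in SEVEN_TI} | {"suvmax": "suvmax_suv", "mv": "mv_ml"}

DEFAULT_METHODS = (RR_SPEC, AR20)
ALL_METHODS = (RR_SPEC, AR15, AR20, AR25)

DEFAULT_DIAMETERS = tuple(range(3, 18, 2))


# ---------------------------------------------------------------------------
# rank statistics
# ---------------------------------------------------------------------------

def spearman_with_flag(x, y) -> tuple[float, bool]:
    """Spearman r with average-rank ties; a zero-variance input is reported
    as r = 0 with a degenerate flag instead of NaN so tables always render."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("Spearman profile needs at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, True
    r = stats.spearmanr(x, y).statistic
    return float(r), False


def spearman_profile(
    features: pd.DataFrame,
    target: str = "n_voxels",
    mv_cap_ml: float | None = None,
) -> pd.DataFrame:
    """Spearman r between each texture index and ``target`` (``n_voxels`` or
    ``suvmax_suv``), per resampling method, optionally restricted to VOIs
    with metabolic volume below ``mv_cap_ml``."""
    if target not in ("n_voxels", "suvmax_suv"):
        raise ValueError(f"unsupported correlation target {target!r}")
    rows = []
    for method, sub in features.groupby("method", sort=False):
        if mv_cap_ml is not None:
            sub = sub[sub.mv_ml < mv_cap_ml]
        for metric, col in METRIC_COLUMNS.items():
            if metric == "mv" or col not in sub.columns:
                continue
            r, degenerate = spearman_with_flag(sub[target], sub[col])
            rows.append(
                dict(
                    metric=metric,
                    method=method,
                    target=target,
                    r=r,
                    n=len(sub),
                    degenerate=degenerate,
                )
            )
    return pd.DataFrame(rows)


def _signed_rank(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank: exact for n <= 25 where possible,
    otherwise normal approximation with continuity correction."""
    diff = a - b
    if np.all(diff == 0):
        return 0.0, 1.0
    n = len(diff)
    if n <= 25:
        try:
            res = stats.wilcoxon(a, b, method="exact")
            return float(res.statistic), float(res.pvalue)
        except ValueError:
            pass
    res = stats.wilcoxon(a, b, correction=True, method="approx")
    return float(res.statistic), float(res.pvalue)


def _rank_sum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U form)."""
    if max(len(a), len(b)) <= 25:
        try:
            res = stats.mannwhitneyu(a, b, method="exact")
            return float(res.statistic), float(res.pvalue)
        except ValueError:
            pass
    res = stats.mannwhitneyu(a, b, method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    features_a: pd.DataFrame,
    features_b: pd.DataFrame,
    paired: bool,
    label_a: str = "a",
    label_b: str = "b",
    include_mv: bool | None = None,
) -> pd.DataFrame:
    """Per-metric Wilcoxon comparison of two feature tables, method by method.

    ``paired`` uses the signed-rank test and requires both tables aligned on
    ``patient_id`` (same patients, e.g. tumor vs relocated-liver VOI);
    unpaired uses the rank-sum test.  Rows cover the seven texture indices
    plus SUVmax, plus metabolic volume for unpaired comparisons (paired VOIs
    share their geometry so MV is identical by construction).  A
    Holm-adjusted p-value column is added within each method.
    """
    if include_mv is None:
        include_mv = not paired
    metrics = list(SEVEN_TI) + ["suvmax"] + (["mv"] if include_mv else [])
    rows = []
    for method in features_a.method.unique():
        sub_a = features_a[features_a.method == method]
        sub_b = features_b[features_b.method == method]
        if paired:
            if len(sub_a) != len(sub_b):
                raise ValueError("paired comparison requires equal group sizes")
            sub_a = sub_a.sort_values("patient_id")
            sub_b = sub_b.sort_values("patient_id")
            if not (sub_a.patient_id.values == sub_b.patient_id.values).all():
                raise ValueError("paired comparison requires aligned patient ids")
        if min(len(sub_a), len(sub_b)) < 2:
            raise ValueError("each group needs at least 2 observations")
        for metric in metrics:
            col = METRIC_COLUMNS[metric]
            va = sub_a[col].to_numpy(dtype=float)
            vb = sub_b[col].to_numpy(dtype=float)
            statistic, p = (_signed_rank if paired else _rank_sum)(va, vb)
            rows.append(
                dict(
                    metric=metric,
                    method=method,
                    group_a=label_a,
                    group_b=label_b,
                    n_a=len(va),
                    n_b=len(vb),
                    statistic=statistic,
                    p_value=p,
                    median_a=float(np.median(va)),
                    q1_a=float(np.percentile(va, 25)),
                    q3_a=float(np.percentile(va, 75)),
                    median_b=float(np.median(vb)),
                    q1_b=float(np.percentile(vb, 25)),
                    q3_b=float(np.percentile(vb, 75)),
                    paired=paired,
                )
            )
    out = pd.DataFrame(rows)
    out["p_holm"] = np.nan
    for method in out.method.unique():
        sel = out.method == method
        out.loc[sel, "p_holm"] = multipletests(out.loc[sel, "p_value"], method="holm")[1]
    return out


# ---------------------------------------------------------------------------
# phantom experiment
# ---------------------------------------------------------------------------

@dataclass
class PhantomResult:
    """Sphere-wise indices, per-size summaries, volume correlations and
    plateau flags for the uniform-phantom experiment."""

    volume: VolumeGrid
    per_sphere: pd.DataFrame
    summary: pd.DataFrame
    correlations: pd.DataFrame
    plateau: pd.DataFrame

    def save_tables(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.per_sphere.to_csv(outdir / "phantom_per_sphere.csv", index=False)
        self.summary.to_csv(outdir / "phantom_summary.csv", index=False)
        self.correlations.to_csv(outdir / "phantom_correlations.csv", index=False)
        self.plateau.to_csv(outdir / "phantom_plateau.csv", index=False)

    def save_plots(self, outdir) -> None:
        _plot_profiles(self.summary, Path(outdir), x="voxel_count")


def run_phantom_experiment(
    spec: PhantomSpec | None = None,
    diameters=DEFAULT_DIAMETERS,
    centers=None,
    methods=DEFAULT_METHODS,
    plateau_tol: float = 0.05,
) -> PhantomResult:
    """Draw spheres of each diameter at each position in the simulated
    phantom and profile the texture indices against the voxel count.

    The plateau detector flags an index once the change of its per-size mean
    between the two largest sphere sizes falls below ``plateau_tol`` times
    the full range of the means (an exactly flat profile counts as
    plateaued).
    """
    spec = spec or PhantomSpec()
    vol = simulate_phantom(spec)
    centers = centers or default_sphere_centers(spec)
    rows = []
    for diameter in diameters:
        for pos_idx, center in enumerate(centers):
            mask = sphere_voi(vol, center, diameter)
            for m in methods:
                ti = extract_ti(vol, mask, m)
                row = ti.as_dict()
                row.update(
                    voi_id=f"d{diameter}_p{pos_idx}",
                    diameter=diameter,
                    position=pos_idx,
                    voxel_count=mask.voxel_count,
                )
                rows.append(row)
    per_sphere = pd.DataFrame(rows)

    ti_cols = [METRIC_COLUMNS[m] for m in METRIC_COLUMNS if m != "mv"]
    grouped = per_sphere.groupby(["method", "diameter"], sort=True)
    summary = grouped[ti_cols + ["voxel_count"]].agg(["mean", "std"])
    summary.columns = ["_".join(c) for c in summary.columns]
    summary = summary.reset_index().sort_values(["method", "voxel_count_mean"])

    corr_rows, plateau_rows = [], []
    for method, sub in summary.groupby("method", sort=False):
        sub = sub.sort_values("voxel_count_mean")
        counts = sub["voxel_count_mean"].to_numpy()
        for metric, col in METRIC_COLUMNS.items():
            if metric == "mv":
                continue
            means = sub[f"{col}_mean"].to_numpy()
            r, degenerate = spearman_with_flag(counts, means)
            corr_rows.append(
                dict(metric=metric, method=method, r=r, n=len(means), degenerate=degenerate)
            )
            rng_ = float(means.max() - means.min())
            plateaued = (
                True if rng_ == 0 else abs(means[-1] - means[-2]) < plateau_tol * rng_
            )
            plateau_rows.append(
                dict(
                    metric=metric,
                    method=method,
                    plateaued=bool(plateaued),
                    last_change_frac=0.0 if rng_ == 0 else abs(means[-1] - means[-2]) / rng_,
                )
            )
    return PhantomResult(
        volume=vol,
        per_sphere=per_sphere,
        summary=summary,
        correlations=pd.DataFrame(corr_rows),
        plateau=pd.DataFrame(plateau_rows),
    )


# ---------------------------------------------------------------------------
# cohort experiment
# ---------------------------------------------------------------------------

@dataclass
class CohortResult:
    """Feature table and study-style outputs for the synthetic cohort."""

    features: pd.DataFrame
    tissue_comparison: pd.DataFrame
    subtype_comparison: pd.DataFrame
    table2_like: pd.DataFrame
    table4_like: pd.DataFrame
    sign_table: pd.DataFrame
    quartiles: pd.DataFrame
    correlations: pd.DataFrame
    exclusions: dict
    ledger: CohortLedger
    failures: list = field(default_factory=list)

    def save_tables(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.features.to_csv(outdir / "cohort_features.csv", index=False)
        self.table2_like.to_csv(outdir / "table2_like.csv")
        self.table4_like.to_csv(outdir / "table4_like.csv")
        self.sign_table.to_csv(outdir / "sign_table.csv")
        self.quartiles.to_csv(outdir / "quartiles.csv", index=False)
        self.correlations.to_csv(outdir / "correlations.csv", index=False)
        self.ledger.table.to_csv(outdir / "ledger.csv", index=False)
        if self.failures:
            pd.DataFrame(self.failures).to_csv(outdir / "failures.csv", index=False)

    def save_plots(self, outdir) -> None:
        tumor = self.features[self.features.tissue == "tumor"].copy()
        tumor["voxel_count"] = tumor["n_voxels"]
        _plot_scatter(tumor, Path(outdir))


def run_cohort_experiment(
    spec: CohortSpec | None = None,
    methods=ALL_METHODS,
    mv_cap_ml: float = 60.0,
    mv_min_ml: float = 2.5,
    segment_kwargs: dict | None = None,
) -> CohortResult:
    """Full synthetic-cohort pipeline: simulate, filter, segment each tumor,
    relocate its geometry into the liver, extract indices under every
    resampling method, and tabulate the tissue and subtype comparisons."""
    spec = spec or CohortSpec()
    segment_kwargs = segment_kwargs or {}
    volumes, ledger = simulate_cohort(spec)
    vol_by_id = {row.patient_id: volumes[i] for i, row in enumerate(ledger.table.itertuples())}
    ledger, tally = apply_exclusions(ledger, mv_min_ml=mv_min_ml)

    rows, failures = [], []
    segmented_ids = []
    for rec in ledger.table.itertuples():
        vol = vol_by_id[rec.patient_id]
        try:
            tumor_mask = _segment_tumor(vol, rec.tumor_center, segment_kwargs)
        except SegmentationError as exc:
            failures.append(dict(patient_id=rec.patient_id, stage="segment", error=str(exc)))
            continue
        if metabolic_volume(tumor_mask, vol.spacing) < mv_min_ml:
            tally["mv_below_min"] += 1
            continue
        liver_mask = relocate_voi(tumor_mask, liver_center(spec))
        segmented_ids.append(rec.patient_id)
        for tissue, mask in (("tumor", tumor_mask), ("liver", liver_mask)):
            for m in methods:
                ti = extract_ti(vol, mask, m, provenance=dict(segmentation=segment_kwargs))
                row = ti.as_dict()
                row.update(
                    patient_id=rec.patient_id,
                    subtype=rec.subtype,
                    tissue=tissue,
                    voi_id=f"{rec.patient_id}_{tissue}",
                )
                rows.append(row)
    features = pd.DataFrame(rows)
    ledger = ledger.subset(segmented_ids)

    tumor = features[features.tissue == "tumor"]
    liver = features[features.tissue == "liver"]
    tissue_cmp = compare_groups(tumor, liver, paired=True, label_a="tumor", label_b="liver")
    adeno = tumor[tumor.subtype == "adenocarcinoma"]
    squam = tumor[tumor.subtype == "squamous"]
    subtype_cmp = compare_groups(
        adeno, squam, paired=False, label_a="adenocarcinoma", label_b="squamous"
    )

    table2 = tissue_cmp.pivot(index="metric", columns="method", values="p_value")
    table4 = subtype_cmp.pivot(index="metric", columns="method", values="p_value")
    order2 = [m for m in METRIC_COLUMNS if m in table2.index]
    order4 = [m for m in METRIC_COLUMNS if m in table4.index]
    table2 = table2.loc[order2]
    table4 = table4.loc[order4]

    sign_table = _sign_table(tissue_cmp, subtype_cmp, method="ar20")
    quartiles = _quartile_table(tissue_cmp, subtype_cmp)
    corr = pd.concat(
        [
            spearman_profile(tumor, "n_voxels", mv_cap_ml=mv_cap_ml).assign(scope="tumor"),
            spearman_profile(tumor, "suvmax_suv", mv_cap_ml=mv_cap_ml).assign(scope="tumor"),
            spearman_profile(liver, "n_voxels", mv_cap_ml=mv_cap_ml).assign(scope="liver"),
        ],
        ignore_index=True,
    )
    return CohortResult(
        features=features,
        tissue_comparison=tissue_cmp,
        subtype_comparison=subtype_cmp,
        table2_like=table2,
        table4_like=table4,
        sign_table=sign_table,
        quartiles=quartiles,
        correlations=corr,
        exclusions=tally,
        ledger=ledger,
        failures=failures,
    )


def _segment_tumor(vol, seed_voxel, segment_kwargs):
    return adaptive_threshold_segment(vol, seed_voxel, **segment_kwargs)


def _sign_table(tissue_cmp: pd.DataFrame, subtype_cmp: pd.DataFrame, method: str) -> pd.DataFrame:
    """Qualitative summary of AR-based median differences: '+' marks the
    group in which the index median is higher."""
    rows = {}
    tc = tissue_cmp[tissue_cmp.method == method].set_index("metric")
    sc = subtype_cmp[subtype_cmp.method == method].set_index("metric")
    metrics = list(SEVEN_TI) + ["suvmax", "mv"]
    for metric in metrics:
        row = {}
        if metric in tc.index:
            higher_a = tc.loc[metric, "median_a"] > tc.loc[metric, "median_b"]
            row["tumor"], row["liver"] = ("+", "-") if higher_a else ("-", "+")
        else:
            row["tumor"] = row["liver"] = "N/A"
        if metric in sc.index:
            higher_a = sc.loc[metric, "median_a"] > sc.loc[metric, "median_b"]
            row["adenocarcinoma"], row["squamous"] = ("+", "-") if higher_a else ("-", "+")
        else:
            row["adenocarcinoma"] = row["squamous"] = "N/A"
        rows[metric] = row
    return pd.DataFrame(rows).T


def _quartile_table(*comparisons: pd.DataFrame) -> pd.DataFrame:
    frames = []
    for cmp_ in comparisons:
        for side in ("a", "b"):
            frames.append(
                cmp_[["metric", "method", f"median_{side}", f"q1_{side}", f"q3_{side}"]]
                .rename(
                    columns={
                        f"median_{side}": "median",
                        f"q1_{side}": "q1",
                        f"q3_{side}": "q3",
                    }
                )
                .assign(group=cmp_[f"group_{side}"])
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# plotting helpers (thin, optional)
# ---------------------------------------------------------------------------

def _plot_profiles(summary: pd.DataFrame, outdir: Path, x: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir.mkdir(parents=True, exist_ok=True)
    metrics = [m for m in METRIC_COLUMNS if m != "mv"]
    for metric in metrics:
        col = METRIC_COLUMNS[metric]
        fig, ax = plt.subplots(figsize=(5, 4))
        for method, sub in summary.groupby("method"):
            sub = sub.sort_values(f"{x}_mean")
            ax.errorbar(
                sub[f"{x}_mean"],
                sub[f"{col}_mean"],
                yerr=sub[f"{col}_std"],
                marker="o",
                capsize=3,
                label=method,
            )
        ax.set_xlabel("voxel count")
        ax.set_ylabel(metric)
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / f"phantom_{metric}.png", dpi=120)
        plt.close(fig)


def _plot_scatter(tumor: pd.DataFrame, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir.mkdir(parents=True, exist_ok=True)
    for xcol, tag in (("voxel_count", "volume"), ("suvmax_suv", "suvmax")):
        for metric in SEVEN_TI:
            fig, ax = plt.subplots(figsize=(5, 4))
            for method, sub in tumor.groupby("method"):
                ax.scatter(sub[xcol], sub[metric], s=12, label=method)
            ax.set_xlabel(xcol)
            ax.set_ylabel(metric)
            ax.legend()
            fig.tight_layout()
            fig.savefig(outdir / f"cohort_{metric}_vs_{tag}.png", dpi=120)
            plt.close(fig)
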