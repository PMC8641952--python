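"""Cohort-level analysis: feature table, PCA, recruitment gain,
correlations and slope comparisons.

The feature table holds one row per cell with the canonical set of
intrinsic properties plus subtype/week/drug labels. PCA is performed on
z-scored columns (the correlation-matrix decomposition) because the
properties carry wildly different units; constant columns are dropped with
a warning and incomplete rows are excluded per analysis (complete-case).

Recruitment gain is summarised, per group of rheobase currents, by the
range (max − min) and the empirical cumulative-proportion curve; a steeper
curve (smaller range) means more synchronous recruitment. Between-group
arithmetic is exposed in both conventions found in practice:
``range_ratio`` (100·range_A/range_B) and ``range_reduction``
(100·(range_B − range_A)/range_B).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
import statsmodels.formula.api as smf

from .errors import DegenerateInputError, InvalidArgumentError
from .pipeline import FEATURE_COLUMNS

logger = logging.getLogger(__name__)

#: Spikes smaller than this (mV from threshold) fail cell inclusion.
MIN_SPIKE_AMPLITUDE_MV = 60.0

LABEL_COLUMNS = ["cell_id", "subtype", "week", "drug", "firing_type"]


@dataclass
class PCAResult:
    loadings: pd.DataFrame          # variables × components
    scores: pd.DataFrame            # cells × components
    variance_explained: np.ndarray  # percent per component
    dropped_columns: list = field(default_factory=list)
    n_cells: int = 0


@dataclass
class RecruitmentSummary:
    ranges: dict                    # group -> pA
    cdfs: dict                      # group -> (sorted values, cum. proportion)
    range_ratio: dict               # (A, B) -> 100·range_A/range_B
    range_reduction: dict           # (A, B) -> 100·(range_B−range_A)/range_B


def build_feature_table(cell_results: list[dict],
                        labels: list[dict] | None = None) -> pd.DataFrame:
    """Assemble per-cell feature dicts into the cohort table.

    Cells whose spike amplitude from threshold is below 60 mV are excluded
    (and logged), mirroring standard recording-quality criteria. Numeric
    columns with more than 50% missing raise a hard error naming the
    column; other missing values stay as NaN.
    """
    rows = []
    for i, res in enumerate(cell_results):
        row = dict(res)
        if labels is not None:
            row.update(labels[i])
        rows.append(row)
    df = pd.DataFrame(rows)
    if "cell_id" in df.columns and df["cell_id"].notna().any():
        dup = df["cell_id"].dropna().duplicated()
        if dup.any():
            raise InvalidArgumentError(
                f"duplicated cell ids: {sorted(df['cell_id'][dup.values])}")

    if "ap_amplitude" in df.columns:
        bad = df["ap_amplitude"] < MIN_SPIKE_AMPLITUDE_MV
        if bad.any():
            for cid in df.loc[bad, "cell_id"] if "cell_id" in df else []:
                logger.warning("excluding cell %s: spike amplitude below "
                               "%.0f mV", cid, MIN_SPIKE_AMPLITUDE_MV)
            df = df.loc[~bad.fillna(False)].reset_index(drop=True)

    numeric = [c for c in df.columns
               if c in FEATURE_COLUMNS and c != "firing_type"]
    for col in numeric:
        frac = df[col].isna().mean()
        if frac > 0.5:
            raise DegenerateInputError(
                f"column {col!r} has {100 * frac:.0f}% missing values")
    return df


def run_pca(table: pd.DataFrame, n_components: int = 10,
            columns: list[str] | None = None) -> PCAResult:
    """Correlation-matrix PCA of the feature table.

    Columns are z-scored; constant columns are dropped with a warning and
    incomplete rows excluded. Scores, loadings and percent variance
    explained are returned; score columns are mutually orthogonal.
    """
    if columns is None:
        columns = [c for c in table.columns
                   if c in FEATURE_COLUMNS and c != "firing_type"
                   and np.issubdtype(table[c].dtype, np.number)]
        if not columns:  # free-form table: use every numeric column
            columns = [c for c in table.columns
                       if np.issubdtype(table[c].dtype, np.number)]
    data = table[columns].astype(float)
    complete = data.dropna()
    if complete.shape[0] < 10:
        raise DegenerateInputError(
            f"need >= 10 complete rows for PCA, got {complete.shape[0]}")
    dropped = [c for c in columns if complete[c].std(ddof=0) == 0]
    if dropped:
        logger.warning("dropping constant columns before PCA: %s", dropped)
        complete = complete.drop(columns=dropped)
    z = (complete - complete.mean()) / complete.std(ddof=0)
    k = min(n_components, z.shape[1], z.shape[0])
    pca = PCA(n_components=k)
    scores = pca.fit_transform(z.values)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        loadings=pd.DataFrame(pca.components_.T, index=z.columns,
                              columns=comp_names),
        scores=pd.DataFrame(scores, index=complete.index,
                            columns=comp_names),
        variance_explained=pca.explained_variance_ratio_ * 100.0,
        dropped_columns=dropped,
        n_cells=complete.shape[0],
    )


def recruitment_gain(groups: dict) -> RecruitmentSummary:
    """Recruitment-gain summary over named groups of rheobase values.

    Per group: range (max − min, pA) and the empirical cumulative-
    proportion curve. Pairwise, for every ordered pair (A, B):
    range_ratio = 100·range_A/range_B and
    range_reduction = 100·(range_B − range_A)/range_B.
    """
    ranges, cdfs = {}, {}
    for name, values in groups.items():
        v = np.sort(np.asarray(values, dtype=float))
        v = v[~np.isnan(v)]
        if v.size < 2:
            raise DegenerateInputError(
                f"group {name!r} needs >= 2 rheobase values, got {v.size}")
        ranges[name] = float(v[-1] - v[0])
        cdfs[name] = (v, np.arange(1, v.size + 1) / v.size)
    ratio, reduction = {}, {}
    for a in ranges:
        for b in ranges:
            if a == b:
                continue
            ratio[(a, b)] = 100.0 * ranges[a] / ranges[b]
            reduction[(a, b)] = 100.0 * (ranges[b] - ranges[a]) / ranges[b]
    return RecruitmentSummary(ranges=ranges, cdfs=cdfs, range_ratio=ratio,
                              range_reduction=reduction)


def combined_percent_reduction(per_drug_percent: list[float]) -> float:
    """Combined effect of independent blockers acting on disjoint current
    components, each expressed as a percent reduction of the same baseline:
    the per-drug percent reductions add."""
    return float(np.sum(per_drug_percent))


def correlate_and_compare(table: pd.DataFrame, x: str, y: str,
                          group_by: str = "subtype") -> dict:
    """Per-group Pearson correlation plus a between-group slope comparison.

    For each group: Pearson r and two-sided p over complete (x, y) pairs;
    groups with zero variance are flagged undefined. Across the first two
    groups, an OLS interaction model ``y ~ x * group`` tests whether the
    regression slopes differ (the interaction coefficient's p-value, with
    a heteroscedasticity-robust HC3 covariance).
    """
    out = {"groups": {}, "slope_comparison": None}
    sub = table[[x, y, group_by]].dropna()
    names = list(dict.fromkeys(sub[group_by]))
    for name in names:
        g = sub[sub[group_by] == name]
        if g.shape[0] < 3:
            out["groups"][name] = {"r": np.nan, "p": np.nan,
                                   "flag": "insufficient_pairs"}
            continue
        if g[x].std(ddof=0) == 0 or g[y].std(ddof=0) == 0:
            out["groups"][name] = {"r": np.nan, "p": np.nan,
                                   "flag": "undefined_correlation"}
            continue
        r, p = stats.pearsonr(g[x], g[y])
        slope = float(np.polyfit(g[x], g[y], 1)[0])
        out["groups"][name] = {"r": float(r), "p": float(p),
                               "slope": slope, "n": int(g.shape[0])}
    if len(names) >= 2:
        two = sub[sub[group_by].isin(names[:2])].copy()
        two = two.rename(columns={x: "_x", y: "_y", group_by: "_g"})
        if (two.groupby("_g")["_x"].std(ddof=0) > 0).all():
            fit = smf.ols("_y ~ _x * C(_g)", data=two).fit(cov_type="HC3")
            inter = [c for c in fit.params.index
                     if c.startswith("_x:C(_g)")]
            if inter:
                out["slope_comparison"] = {
                    "slope_difference": float(fit.params[inter[0]]),
                    "p": float(fit.pvalues[inter[0]]),
                    "groups": names[:2],
                }
    return out


def table_to_csv(table: pd.DataFrame, path, units: dict | None = None) -> None:
    """Write the cohort table as CSV plus a JSON sidecar with labels/units."""
    import json
    table.to_csv(path, index=False)
    side = {"label_columns": [c for c in LABEL_COLUMNS if c in table.columns],
            "units": units or DEFAULT_UNITS}
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(side, fh, indent=1, sort_keys=True)


def table_from_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


DEFAULT_UNITS = {
    "RMP": "mV", "R_in_initial": "MOhm", "R_in_ss": "MOhm", "tau_m": "ms",
    "C_m": "pF", "rheobase_step": "pA", "rheobase_ramp": "pA",
    "threshold_V": "mV", "ap_amplitude": "mV", "ap_rise_time": "ms",
    "ap_half_width": "ms", "mahp_amplitude": "mV", "mahp_half_width": "ms",
    "onset_latency": "ms", "rate_at_rheobase": "Hz", "rate_at_2x": "Hz",
    "max_rate": "Hz", "subprimary_gain": "Hz/pA", "delta_I": "pA",
    "hysteresis_type": "1-4", "accel_onset_V": "mV", "accel_amplitude": "mV",
    "ePIC": "pA", "sag_amplitude": "mV", "g_sag": "nS",
    "pic_onset_V": "mV", "pic_peak_V": "mV", "pic_amplitude": "pA",
    "pic_density": "pA/pF", "ih_amp_-70": "pA", "ih_amp_-110": "pA",
    "ih_tau_-110": "ms", "resting_ih": "pA", "resting_ih_density": "pA/pF",
}
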