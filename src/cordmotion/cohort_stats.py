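"""Cohort-level statistics: exclusions, biometrics, segmental comparisons,
ICC reliability, and Spearman correlations.

Conventions follow common clinical-stats practice: sample SD (n-1
denominator), mid-rank ties, pairwise deletion of missing covariates, and
the two-way mixed-model absolute-agreement average-measures ICC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, StructuralError
from .velocity_pipeline import READOUT_NAMES

KEY_COLS = ["subject_id", "scan_id", "rater_id", "segment", "corrected"]


@dataclass(frozen=True)
class CohortTable:
    """Readouts joined with subject covariates and per-segment anatomy.

    `readouts` is wide (one row per subject x scan x rater x segment x
    corrected-flag, columns for the four readouts plus drift_estimate and
    rr_interval).  `subjects` carries one row per subject with covariates
    and the exclusion flag; `anatomy` one row per subject x segment.
    """

    readouts: pd.DataFrame
    subjects: pd.DataFrame
    anatomy: pd.DataFrame | None = None

    def __post_init__(self):
        for col in KEY_COLS + list(READOUT_NAMES):
            if col not in self.readouts.columns:
                raise StructuralError(f"readouts table missing column {col!r}")
        if self.readouts.duplicated(KEY_COLS).any():
            raise StructuralError("duplicate (subject, scan, rater, segment) keys")
        for col in ("subject_id", "excluded", "exclusion_reason"):
            if col not in self.subjects.columns:
                raise StructuralError(f"subjects table missing column {col!r}")
        bad = self.subjects["excluded"] & (
            self.subjects["exclusion_reason"].fillna("").astype(str).str.len() == 0)
        if bad.any():
            raise StructuralError("excluded subjects must carry a non-empty reason")

    @property
    def subject_ids(self) -> list[str]:
        return sorted(self.subjects["subject_id"].unique())

    def long(self) -> pd.DataFrame:
        """Long format: one row per (key, readout name, value)."""
        return self.readouts.melt(
            id_vars=KEY_COLS, value_vars=list(READOUT_NAMES),
            var_name="readout", value_name="value")

    def select(self, corrected: bool = True, scan_id: str | None = None,
               rater_id: str | None = None) -> pd.DataFrame:
        df = self.readouts[self.readouts["corrected"] == corrected]
        if scan_id is not None:
            df = df[df["scan_id"] == scan_id]
        if rater_id is not None:
            df = df[df["rater_id"] == rater_id]
        return df

    def primary_view(self, corrected: bool = True) -> pd.DataFrame:
        """First scan, first rater — the default substrate for group stats."""
        df = self.select(corrected=corrected)
        scan = sorted(df["scan_id"].unique())[0]
        rater = sorted(df["rater_id"].unique())[0]
        return df[(df["scan_id"] == scan) & (df["rater_id"] == rater)]


def build_cohort_table(readouts: pd.DataFrame, subjects: pd.DataFrame,
                       anatomy: pd.DataFrame | None = None) -> CohortTable:
    subjects = subjects.copy()
    if "excluded" not in subjects.columns:
        subjects["excluded"] = False
    if "exclusion_reason" not in subjects.columns:
        subjects["exclusion_reason"] = ""
    return CohortTable(readouts=readouts.copy(), subjects=subjects, anatomy=anatomy)


# ---------------------------------------------------------------------------
# filtering and biometrics
# ---------------------------------------------------------------------------

def apply_exclusions(cohort: CohortTable) -> tuple[CohortTable, int, int]:
    """Drop flagged subjects everywhere; returns (cohort, n_before, n_after)."""
    n_before = cohort.subjects["subject_id"].nunique()
    keep = cohort.subjects.loc[~cohort.subjects["excluded"], "subject_id"]
    keep_set = set(keep)
    n_after = len(keep_set)
    if n_after == 0:
        warnings.warn("all subjects excluded; cohort is empty", stacklevel=2)
    filtered = CohortTable(
        readouts=cohort.readouts[cohort.readouts["subject_id"].isin(keep_set)]
        .reset_index(drop=True),
        subjects=cohort.subjects[cohort.subjects["subject_id"].isin(keep_set)]
        .reset_index(drop=True),
        anatomy=None if cohort.anatomy is None else
        cohort.anatomy[cohort.anatomy["subject_id"].isin(keep_set)]
        .reset_index(drop=True),
    )
    return filtered, n_before, n_after


def derive_biometrics(subjects: pd.DataFrame) -> pd.DataFrame:
    """Add mean_systolic, mean_diastolic and mean_arterial_pressure columns.

    Means average the before/after scan readings; MAP uses the one-third
    pulse-pressure rule on those means.  Missing inputs propagate as NaN.
    """
    out = subjects.copy()
    out["mean_systolic"] = (out["sys_before"] + out["sys_after"]) / 2.0
    out["mean_diastolic"] = (out["dia_before"] + out["dia_after"]) / 2.0
    out["mean_arterial_pressure"] = (
        out["mean_diastolic"] + (out["mean_systolic"] - out["mean_diastolic"]) / 3.0)
    return out


def mean_arterial_pressure(systolic: float, diastolic: float) -> float:
    """MAP = diastolic + (systolic - diastolic) / 3."""
    return diastolic + (systolic - diastolic) / 3.0


# ---------------------------------------------------------------------------
# segment summaries and Friedman comparisons
# ---------------------------------------------------------------------------

def segment_summary(cohort: CohortTable, readout: str,
                    corrected: bool = True) -> pd.DataFrame:
    """Per-segment group mean, sample SD and n for one readout."""
    _check_readout(readout)
    df = cohort.primary_view(corrected=corrected)
    if df["subject_id"].nunique() < 2:
        raise InsufficientDataError("segment summary needs at least 2 subjects")
    grouped = df.groupby("segment")[readout]
    out = grouped.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count")
    return out.reset_index()


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    p_value: float
    n_subjects: int
    n_segments: int
    pairwise: pd.DataFrame      # seg_a, seg_b, z, p_raw, p_adj


def friedman_intersegment(cohort: CohortTable, readout: str,
                          corrected: bool = True) -> FriedmanResult:
    """Friedman omnibus test across segments plus Dunn pairwise follow-up.

    Subjects missing any segment are dropped (complete-block design).
    Pairwise z statistics use the within-subject mean ranks with the
    standard error sqrt(k(k+1)/(6n)); p-values are Bonferroni-adjusted
    over the k(k-1)/2 comparisons.
    """
    _check_readout(readout)
    df = cohort.primary_view(corrected=corrected)
    wide = df.pivot(index="subject_id", columns="segment", values=readout)
    incomplete = wide.isna().any(axis=1)
    if incomplete.any():
        warnings.warn(f"dropping {int(incomplete.sum())} subject(s) with "
                      "missing segments from the Friedman test", stacklevel=2)
        wide = wide[~incomplete]
    n, k = wide.shape
    if k < 3 or n < 2:
        raise InsufficientDataError(
            f"Friedman test needs >= 3 segments and >= 2 subjects (got {k}, {n})")
    if (wide.max(axis=1) == wide.min(axis=1)).all():
        stat, p = 0.0, 1.0      # every subject fully tied: no evidence at all
    else:
        stat, p = stats.friedmanchisquare(*(wide[c].to_numpy() for c in wide.columns))
    ranks = wide.rank(axis=1)          # mid-ranks within subject
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    rows = []
    segs = list(wide.columns)
    n_pairs = k * (k - 1) // 2
    for a in range(k):
        for b in range(a + 1, k):
            z = (mean_ranks.iloc[a] - mean_ranks.iloc[b]) / se
            p_raw = 2.0 * stats.norm.sf(abs(z))
            rows.append({"seg_a": segs[a], "seg_b": segs[b], "z": z,
                         "p_raw": p_raw, "p_adj": min(1.0, p_raw * n_pairs)})
    return FriedmanResult(statistic=float(stat), p_value=float(p),
                          n_subjects=n, n_segments=k,
                          pairwise=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ICCResult:
    """Two-way mixed-model ICC with its F-test."""

    icc: float
    p_value: float
    n_subjects: int
    k: int
    model: str = "two-way mixed, absolute agreement, average measures"

    def __post_init__(self):
        if np.isfinite(self.icc) and self.icc > 1.0 + 1e-12:
            raise ValueError("ICC cannot exceed 1")


def icc_two_way(data, icc_type: str = "absolute_agreement",
                unit: str = "average") -> ICCResult:
    """ICC from the two-way ANOVA decomposition of an n x k matrix.

    For absolute agreement, average measures (McGraw & Wong ICC(A,k)):

        ICC = (MS_R - MS_E) / (MS_R + (MS_C - MS_E) / n)

    with MS_R the between-subject, MS_C the between-measurement and MS_E
    the residual mean square.  The p-value is the F test of
    MS_R / MS_E on (n-1, (n-1)(k-1)) degrees of freedom.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be a 2-D subjects x measurements matrix")
    if np.isnan(x).any():
        raise ValueError("ICC input must not contain missing cells")
    n, k = x.shape
    if n < 2 or k < 2:
        raise InsufficientDataError("ICC needs >= 2 subjects and >= 2 measurements")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))

    if icc_type == "absolute_agreement":
        if unit == "average":
            denom = ms_r + (ms_c - ms_e) / n
        elif unit == "single":
            denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
        else:
            raise ValueError(f"unknown unit {unit!r}")
    elif icc_type == "consistency":
        denom = ms_r if unit == "average" else ms_r + (k - 1) * ms_e
    else:
        raise ValueError(f"unknown icc_type {icc_type!r}")

    numer = ms_r - ms_e
    if denom <= 0:
        warnings.warn("non-positive ICC denominator (no between-subject "
                      "variance); reporting ICC 0", stacklevel=2)
        icc = 0.0
    else:
        icc = numer / denom
        if icc <= 0:
            warnings.warn("ICC is non-positive (between-subject variance does "
                          "not exceed error variance)", stacklevel=2)
    if ms_e == 0:
        p = 0.0 if ms_r > 0 else 1.0
    else:
        f = ms_r / ms_e
        p = float(stats.f.sf(f, n - 1, (n - 1) * (k - 1)))
    model = f"two-way mixed, {icc_type.replace('_', ' ')}, {unit} measures"
    return ICCResult(icc=float(min(icc, 1.0)), p_value=p, n_subjects=n, k=k,
                     model=model)


def reliability_report(cohort: CohortTable, mode: str,
                       use_correction: bool = True) -> pd.DataFrame:
    """ICC per segment x readout for inter-rater or test-retest agreement.

    `inter_rater` pairs the two raters on the first scan; `test_retest`
    pairs the two scans for the first rater.  Subjects missing either
    member of a pair are dropped with a warning.
    """
    if mode == "inter_rater":
        pair_col = "rater_id"
        df = cohort.select(corrected=use_correction)
        df = df[df["scan_id"] == sorted(df["scan_id"].unique())[0]]
    elif mode == "test_retest":
        pair_col = "scan_id"
        df = cohort.select(corrected=use_correction)
        df = df[df["rater_id"] == sorted(df["rater_id"].unique())[0]]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    levels = sorted(df[pair_col].unique())
    if len(levels) != 2:
        raise InsufficientDataError(
            f"{mode} reliability needs exactly 2 {pair_col} levels; got {levels}")
    rows = []
    for segment in sorted(df["segment"].unique()):
        seg = df[df["segment"] == segment]
        for readout in READOUT_NAMES:
            wide = seg.pivot(index="subject_id", columns=pair_col, values=readout)
            dropped = wide.isna().any(axis=1)
            if dropped.any():
                warnings.warn(f"{segment}/{readout}: dropping "
                              f"{int(dropped.sum())} unpaired subject(s)",
                              stacklevel=2)
                wide = wide[~dropped]
            res = icc_two_way(wide.to_numpy())
            rows.append({"segment": segment, "readout": readout,
                         "icc": res.icc, "p_value": res.p_value,
                         "n": res.n_subjects})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def _check_readout(readout: str) -> None:
    if readout not in READOUT_NAMES:
        raise ValueError(f"unknown readout {readout!r}; expected one of {READOUT_NAMES}")


def _join_covariate(cohort: CohortTable, df: pd.DataFrame, covariate: str
                    ) -> pd.DataFrame:
    if covariate in df.columns:
        return df.rename(columns={covariate: "_cov"}) if covariate != "_cov" else df
    if covariate in cohort.subjects.columns:
        cov = cohort.subjects[["subject_id", covariate]].rename(
            columns={covariate: "_cov"})
        return df.merge(cov, on="subject_id", how="left")
    if cohort.anatomy is not None and covariate in cohort.anatomy.columns:
        cov = cohort.anatomy[["subject_id", "segment", covariate]].rename(
            columns={covariate: "_cov"})
        return df.merge(cov, on=["subject_id", "segment"], how="left")
    raise KeyError(f"covariate {covariate!r} not found in readouts, subjects "
                   "or anatomy tables")


def spearman_correlations(cohort: CohortTable, readout: str, covariate: str,
                          scope: str = "per_segment",
                          corrected: bool = True) -> pd.DataFrame:
    """Spearman rho between a readout and a covariate.

    `per_segment` gives one rho per segment (n = subjects); `pooled_all_segments`
    stacks every segment-level observation into a single correlation, treating
    them as independent (caveat: within-subject correlation is ignored).
    A constant covariate yields NaN with a reason, not an error.
    """
    _check_readout(readout)
    df = cohort.primary_view(corrected=corrected)
    if readout == covariate:
        df = df.assign(_cov=df[readout])
    else:
        df = _join_covariate(cohort, df, covariate)
    if scope == "per_segment":
        groups = [(seg, sub) for seg, sub in df.groupby("segment")]
    elif scope == "pooled_all_segments":
        groups = [("all", df)]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    rows = []
    for name, sub in groups:
        pairs = sub[[readout, "_cov"]].dropna()
        row = {"scope": name, "readout": readout, "covariate": covariate,
               "n": len(pairs), "rho": np.nan, "p_value": np.nan, "note": ""}
        if len(pairs) < 4:
            row["note"] = "fewer than 4 complete pairs"
        elif pairs["_cov"].nunique() == 1:
            row["note"] = "constant covariate; rho undefined"
        elif pairs[readout].nunique() == 1:
            row["note"] = "constant readout; rho undefined"
        else:
            rho, p = stats.spearmanr(pairs[readout], pairs["_cov"])
            row["rho"], row["p_value"] = float(rho), float(p)
        rows.append(row)
    return pd.DataFrame(rows)


def cluster_bootstrap_pooled_p(cohort: CohortTable, readout: str, covariate: str,
                               n_boot: int = 1000, seed: int = 0,
                               corrected: bool = True) -> float:
    """Supplementary subject-level bootstrap p for the pooled correlation.

    Resamples whole subjects to respect within-subject clustering that the
    primary pooled estimate ignores.
    """
    df = cohort.primary_view(corrected=corrected)
    df = _join_covariate(cohort, df, covariate)[["subject_id", readout, "_cov"]].dropna()
    rho_obs = stats.spearmanr(df[readout], df["_cov"]).statistic
    subjects = df["subject_id"].unique()
    rng = np.random.default_rng(seed)
    hits = 0
    groups = {s: g for s, g in df.groupby("subject_id")}
    for _ in range(n_boot):
        sample = rng.choice(subjects, size=len(subjects), replace=True)
        boot = pd.concat([groups[s] for s in sample], ignore_index=True)
        # center the null by permuting covariates across subjects
        perm = rng.permutation(boot["_cov"].to_numpy())
        rho = stats.spearmanr(boot[readout], perm).statistic
        if abs(rho) >= abs(rho_obs):
            hits += 1
    return (hits + 1) / (n_boot + 1)
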