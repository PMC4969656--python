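"""Reproducibility and uptake-time statistics.

Implements the statistical layer of a dual-time-point volumetric PET
study: intraclass correlation (ICC) between repeated delineations,
paired t-tests with Holm step-down adjustment across the parameter
family, delayed-to-early (D/E) ratios of phase means, Bland-Altman
limits of agreement, and the report tables.

Observation design: two operators each delineate every lesion twice,
giving four observations per lesion per phase (Op1Ob1, Op1Ob2, Op2Ob1,
Op2Ob2).  Intra-operator reproducibility uses 2 pairings (Op1Ob1 vs
Op1Ob2; Op2Ob1 vs Op2Ob2); inter-operator reproducibility uses the 4
cross pairings.

The default ICC form is the two-way random-effects, absolute-agreement,
single-measures coefficient (ICC(2,1)), computed from the ANOVA mean
squares; the one-way (ICC(1,1)) and consistency (ICC(3,1)) forms are
available via ``model``.  Which form the field's reports use is rarely
stated, so the model is recorded alongside every coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .metrics import VolumetricResult
from .synthetic import CohortRecord

__all__ = [
    "ObservationKey",
    "IccResult",
    "PairedTResult",
    "PhaseComparison",
    "BlandAltman",
    "MissingDataError",
    "OBSERVATION_KEYS",
    "INTRA_PAIRINGS",
    "INTER_PAIRINGS",
    "icc",
    "paired_t",
    "holm_adjust",
    "bland_altman",
    "results_to_frame",
    "reproducibility_table",
    "phase_comparison",
    "delayed_to_early_ratio",
    "cohort_summary",
]

ObservationKey = tuple[int, int]  # (operator_id, observation_id)

OBSERVATION_KEYS: tuple[ObservationKey, ...] = ((1, 1), (1, 2), (2, 1), (2, 2))
INTRA_PAIRINGS = (((1, 1), (1, 2)), ((2, 1), (2, 2)))
INTER_PAIRINGS = (((1, 1), (2, 1)), ((1, 1), (2, 2)), ((1, 2), (2, 1)), ((1, 2), (2, 2)))


class MissingDataError(ValueError):
    """An expected observation or phase is absent from the results."""


@dataclass
class IccResult:
    icc: float  # NaN when degenerate
    n_subjects: int
    model: str
    degenerate: bool = False
    pairing: tuple[ObservationKey, ObservationKey] | None = None


@dataclass
class PairedTResult:
    t: float
    p: float
    n: int
    degenerate: bool = False  # all paired differences equal (zero variance)


@dataclass
class BlandAltman:
    """Agreement statistics for paired measurements (b - a differences)."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray


def icc(a, b, model: str = "icc2", pairing=None) -> IccResult:
    """Intraclass correlation between two paired measurement vectors.

    ``model``: ``"icc2"`` two-way random, absolute agreement, single
    measures (default); ``"icc3"`` two-way mixed, consistency;
    ``"icc1"`` one-way random.  Computed from the ANOVA sums of squares
    of the subjects x raters table.  Identical non-constant vectors give
    exactly 1; zero between-subject variance is flagged as degenerate
    (NaN) rather than silently reported.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D vectors of equal length")
    n = a.size
    if n < 3:
        raise ValueError("ICC needs at least 3 paired subjects")
    if model not in ("icc1", "icc2", "icc3"):
        raise ValueError(f"unknown ICC model {model!r}")

    data = np.column_stack([a, b])  # n subjects x k=2 raters
    k = 2
    grand = data.mean()
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    ss_total = float(((data - grand) ** 2).sum())
    ss_rows = k * float(((subj_means - grand) ** 2).sum())
    ss_cols = n * float(((rater_means - grand) ** 2).sum())
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)

    msr = ss_rows / (n - 1)  # between subjects
    msc = ss_cols / (k - 1)  # between raters
    mse = ss_err / ((n - 1) * (k - 1))  # residual
    msw = (ss_cols + ss_err) / (n * (k - 1))  # within subjects (one-way)

    if msr == 0.0:
        # no between-subject variance: agreement is undefined
        return IccResult(float("nan"), n, model, degenerate=True, pairing=pairing)
    if np.array_equal(a, b):
        return IccResult(1.0, n, model, pairing=pairing)

    if model == "icc1":
        val = (msr - msw) / (msr + (k - 1) * msw)
    elif model == "icc3":
        val = (msr - mse) / (msr + (k - 1) * mse)
    else:  # icc2: absolute agreement
        val = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return IccResult(float(val), n, model, pairing=pairing)


def paired_t(a, b) -> PairedTResult:
    """Classical paired t-test (two-sided).

    All-equal differences (including b == a and constant shifts) have
    zero variance; they are flagged degenerate instead of yielding an
    infinite statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("paired_t needs two equal-length vectors with n >= 2")
    d = b - a
    if np.ptp(d) == 0.0:
        return PairedTResult(float("nan"), float("nan"), a.size, degenerate=True)
    res = sps.ttest_rel(b, a)
    return PairedTResult(float(res.statistic), float(res.pvalue), a.size)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def bland_altman(a, b) -> BlandAltman:
    """Bland-Altman agreement between paired vectors (differences b - a)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("bland_altman needs two equal-length vectors with n >= 2")
    diffs = b - a
    means = (a + b) / 2.0
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    return BlandAltman(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        means=means,
        diffs=diffs,
    )


# --- tidy results and report tables ---------------------------------------


def results_to_frame(results: list[VolumetricResult]) -> pd.DataFrame:
    """Long-format frame: one row per (subject, phase, observation, parameter).

    Each :class:`VolumetricResult` contributes an ``MTV_<label>`` and a
    ``TLG_<label>`` row; the observation-level ``SUVmax`` row is emitted
    once per (subject, phase, operator, observation).
    """
    rows = []
    seen_suvmax = set()
    for r in results:
        base = dict(
            subject_id=r.subject_id,
            phase=r.phase,
            operator_id=r.operator_id,
            observation_id=r.observation_id,
        )
        obs_key = (r.subject_id, r.phase, r.operator_id, r.observation_id)
        if obs_key not in seen_suvmax:
            seen_suvmax.add(obs_key)
            rows.append({**base, "parameter": "SUVmax", "value": r.suv_max,
                         "success": True})
        label = r.method.label
        rows.append({**base, "parameter": f"MTV_{label}", "value": r.mtv_ml,
                     "success": r.success})
        rows.append({**base, "parameter": f"TLG_{label}", "value": r.tlg_ml_suv,
                     "success": r.success})
    return pd.DataFrame(rows)


def _pivot_observations(tidy: pd.DataFrame, phase: str, parameter: str) -> pd.DataFrame:
    sub = tidy[(tidy["phase"] == phase) & (tidy["parameter"] == parameter)]
    table = sub.pivot_table(
        index="subject_id", columns=["operator_id", "observation_id"],
        values="value", aggfunc="first", sort=True,
    )
    for key in OBSERVATION_KEYS:
        if key not in table.columns or table[key].isna().any():
            raise MissingDataError(
                f"missing observation Op{key[0]}Ob{key[1]} for {parameter} ({phase})"
            )
    return table


def _parameter_order(tidy: pd.DataFrame) -> list[str]:
    """Report order: SUVmax, then MTV variants, then TLG variants."""
    seen = list(dict.fromkeys(tidy["parameter"]))
    rank = {"SUVmax": 0, "MTV": 1, "TLG": 2}
    return sorted(seen, key=lambda p: (rank.get(p.split("_")[0], 3), seen.index(p)))


def reproducibility_table(
    tidy: pd.DataFrame, phase: str, icc_model: str = "icc2"
) -> pd.DataFrame:
    """Per-parameter observation means +- SD and the six reproducibility ICCs.

    Columns mirror the standard reproducibility report: mean and SD per
    observation (Op1Ob1 ... Op2Ob2), the 2 intra-operator ICCs, and the 4
    inter-operator ICCs.  Requires all four observations for every lesion.
    """
    rows = []
    for param in _parameter_order(tidy):
        table = _pivot_observations(tidy, phase, param)
        row: dict = {"parameter": param, "n": len(table)}
        for op, ob in OBSERVATION_KEYS:
            col = table[(op, ob)].to_numpy()
            row[f"mean_op{op}ob{ob}"] = col.mean()
            row[f"sd_op{op}ob{ob}"] = col.std(ddof=1)
        for (ka, kb) in INTRA_PAIRINGS:
            res = icc(table[ka].to_numpy(), table[kb].to_numpy(),
                      model=icc_model, pairing=(ka, kb))
            row[f"icc_intra_op{ka[0]}"] = res.icc
        for (ka, kb) in INTER_PAIRINGS:
            res = icc(table[ka].to_numpy(), table[kb].to_numpy(),
                      model=icc_model, pairing=(ka, kb))
            row[f"icc_inter_{ka[0]}{ka[1]}_{kb[0]}{kb[1]}"] = res.icc
        row["icc_model"] = icc_model
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PhaseComparison:
    """One row of the early-vs-delayed comparison table."""

    parameter: str
    early_mean: float
    early_sd: float
    delayed_mean: float
    delayed_sd: float
    de_ratio: float
    t: float
    p_raw: float
    p_holm: float
    n: int
    degenerate: bool = False


def delayed_to_early_ratio(early_mean: float, delayed_mean: float) -> float:
    """D/E: ratio of the delayed-phase mean to the early-phase mean."""
    return delayed_mean / early_mean


def phase_comparison(
    tidy: pd.DataFrame,
    operator_id: int = 1,
    observation_id: int = 1,
    family: list[str] | None = None,
) -> pd.DataFrame:
    """Early-vs-delayed comparison per parameter, Holm-adjusted as one family.

    Uses one observation (default Op1Ob1) per subject and phase.  D/E is
    the ratio of the phase means (not the mean of per-subject ratios).
    Degenerate paired t (all differences equal) is flagged, not given a
    p-value.
    """
    params = family if family is not None else _parameter_order(tidy)
    sub = tidy[(tidy["operator_id"] == operator_id)
               & (tidy["observation_id"] == observation_id)]
    rows: list[PhaseComparison] = []
    for param in params:
        wide = sub[sub["parameter"] == param].pivot_table(
            index="subject_id", columns="phase", values="value", aggfunc="first",
        )
        for ph in ("early", "delayed"):
            if ph not in wide.columns or wide[ph].isna().any():
                raise MissingDataError(f"missing {ph}-phase values for {param}")
        e = wide["early"].to_numpy()
        d = wide["delayed"].to_numpy()
        tt = paired_t(e, d)
        rows.append(PhaseComparison(
            parameter=param,
            early_mean=e.mean(), early_sd=e.std(ddof=1),
            delayed_mean=d.mean(), delayed_sd=d.std(ddof=1),
            de_ratio=delayed_to_early_ratio(e.mean(), d.mean()),
            t=tt.t, p_raw=tt.p, p_holm=float("nan"), n=tt.n,
            degenerate=tt.degenerate,
        ))
    df = pd.DataFrame([vars(r) for r in rows])
    ok = ~df["degenerate"] & df["p_raw"].notna()
    if ok.any():
        df.loc[ok, "p_holm"] = holm_adjust(df.loc[ok, "p_raw"].to_numpy())
    return df


def cohort_summary(records: list[CohortRecord]) -> dict:
    """Summary statistics of a patient-characteristics table.

    Means +- SD and ranges for weight, dosage and dosage/weight, plus
    counts by pathology and stage.  An empty record list yields an empty
    summary rather than an error.
    """
    if not records:
        return {"n": 0, "pathology_counts": {}, "stage_counts": {}}
    df = pd.DataFrame([vars(r) for r in records])

    def describe(col: str) -> dict:
        s = df[col]
        return {
            "mean": float(s.mean()),
            "sd": float(s.std(ddof=1)),
            "min": float(s.min()),
            "max": float(s.max()),
        }

    return {
        "n": len(df),
        "weight_kg": describe("weight_kg"),
        "dosage_MBq": describe("dosage_MBq"),
        "dosage_per_weight_MBq_kg": describe("dosage_per_weight_MBq_kg"),
        "pathology_counts": df["pathology"].value_counts().to_dict(),
        "stage_counts": df["stage"].value_counts().to_dict(),
    }
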