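"""Cross-modality conversion factors and the paired Wilcoxon design.

For every subject/side/site/plane two unitless factors are formed:

* ``CBCT_IAC_over_MRI_IAN`` — canal diameter on CBCT divided by nerve
  diameter on MRI, and
* ``MRI_IAC_over_MRI_IAN`` — canal diameter on MRI divided by the same
  nerve diameter.

Factors are summarized as the arithmetic mean and sample SD (ddof = 1) of
the *per-observation ratios* over all subjects and sides — deliberately not
the ratio of mean diameters, which is a different (and generally smaller)
quantity.  For inference the observations are first averaged over the right
and left sides, leaving one value per participant, and the per-subject
difference between the two factor types is tested against zero with a
one-sample Wilcoxon signed-rank test at alpha = 0.05 (exact null
distribution for n <= 25 without ties, normal approximation with continuity
and tie correction otherwise; zero differences dropped before ranking by
default, Pratt handling available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, InputError

FACTOR_TYPES = ("CBCT_IAC_over_MRI_IAN", "MRI_IAC_over_MRI_IAN")
_NUMERATOR_MODALITY = {"CBCT_IAC_over_MRI_IAN": "CBCT", "MRI_IAC_over_MRI_IAN": "MRI"}


@dataclass
class ConversionSummary:
    site: str
    plane: str
    factor_type: str
    n_observations: int
    mean: float
    sd: float  # NaN when n == 1 (undefined)


@dataclass
class WilcoxonResult:
    site: str
    plane: str
    n_subjects: int
    statistic: float
    p_value: float
    zero_handling: str
    alpha: float = 0.05
    degenerate: bool = False

    @property
    def reject_null(self) -> bool:
        return (not self.degenerate) and self.p_value <= self.alpha


def compute_observations(diameters: pd.DataFrame) -> pd.DataFrame:
    """Per-observation conversion factors from a tidy diameter table.

    ``diameters`` needs columns subject_id, side, site, structure, modality,
    plane, diameter_mm.  For each (subject, side, site, plane) with an
    IAN-MRI denominator, one row per available factor type is produced;
    incomplete pairs are skipped.  Returns a tidy frame with columns
    subject_id, side, site, plane, factor_type, value.
    """
    req = {"subject_id", "side", "site", "structure", "modality", "plane", "diameter_mm"}
    missing = req - set(diameters.columns)
    if missing:
        raise InputError(f"diameter table lacks columns {sorted(missing)}")
    keys = ["subject_id", "side", "site", "plane"]
    wide = diameters.pivot_table(
        index=keys, columns=["structure", "modality"], values="diameter_mm", aggfunc="first"
    )
    rows = []
    for idx, row in wide.iterrows():
        ian = row.get(("IAN", "MRI"), np.nan)
        if np.isnan(ian):
            continue
        if ian <= 0:
            raise DataError(f"non-positive IAN diameter for {dict(zip(keys, idx))}")
        for factor_type in FACTOR_TYPES:
            iac = row.get(("IAC", _NUMERATOR_MODALITY[factor_type]), np.nan)
            if np.isnan(iac):
                continue
            rows.append(dict(zip(keys, idx)) | {"factor_type": factor_type,
                                                "value": float(iac / ian)})
    return pd.DataFrame(rows, columns=keys + ["factor_type", "value"])


def summarize(
    observations: pd.DataFrame, site: str, plane: str, factor_type: str
) -> ConversionSummary:
    """Mean and sample SD (ddof = 1) of the per-observation ratios."""
    sel = observations[
        (observations["site"] == site)
        & (observations["plane"] == plane)
        & (observations["factor_type"] == factor_type)
    ]["value"].to_numpy(dtype=float)
    if sel.size == 0:
        raise InputError(f"no observations for {site}/{plane}/{factor_type}")
    sd = float(np.std(sel, ddof=1)) if sel.size > 1 else float("nan")
    return ConversionSummary(
        site=site,
        plane=plane,
        factor_type=factor_type,
        n_observations=int(sel.size),
        mean=float(np.mean(sel)),
        sd=sd,
    )


def side_average(observations: pd.DataFrame) -> pd.DataFrame:
    """Average the two sides, leaving one observation per participant.

    Grouped by subject/site/plane/factor_type; a subject with a single side
    keeps that side's value.
    """
    if observations.empty:
        return observations.copy()
    return (
        observations.groupby(["subject_id", "site", "plane", "factor_type"], as_index=False)[
            "value"
        ].mean()
    )


def compare_factors(
    per_subject: pd.DataFrame,
    site: str,
    plane: str,
    zero_handling: str = "drop",
    alpha: float = 0.05,
    min_n_warn: int = 6,
) -> WilcoxonResult:
    """One-sample Wilcoxon signed-rank test on per-subject factor differences.

    ``per_subject`` is a side-averaged observation frame containing both
    factor types; subjects present for both types at the given site/plane
    contribute one difference (CBCT-based minus MRI-based factor).  The null
    hypothesis is that the difference between the two conversion factors is
    zero.
    """
    if zero_handling not in ("drop", "pratt"):
        raise InputError("zero_handling must be 'drop' or 'pratt'")
    sel = per_subject[(per_subject["site"] == site) & (per_subject["plane"] == plane)]
    wide = sel.pivot_table(index="subject_id", columns="factor_type", values="value")
    if any(ft not in wide.columns for ft in FACTOR_TYPES):
        raise InputError(f"need both factor types at {site}/{plane}")
    paired = wide.dropna(subset=list(FACTOR_TYPES))
    diffs = (paired[FACTOR_TYPES[0]] - paired[FACTOR_TYPES[1]]).to_numpy(dtype=float)
    n = diffs.size
    if n == 0:
        raise InputError(f"no paired subjects at {site}/{plane}")
    if n < min_n_warn:
        warnings.warn(
            f"only {n} paired subjects at {site}/{plane}; the signed-rank test "
            "has little power below 6",
            stacklevel=2,
        )
    if np.all(diffs == 0):
        return WilcoxonResult(
            site=site, plane=plane, n_subjects=n, statistic=0.0, p_value=1.0,
            zero_handling=zero_handling, alpha=alpha, degenerate=True,
        )
    nonzero = diffs[diffs != 0]
    ties = len(np.unique(np.abs(nonzero))) < len(nonzero)
    method = "exact" if (len(nonzero) <= 25 and not ties and zero_handling == "drop") else "approx"
    res = stats.wilcoxon(
        diffs,
        zero_method="wilcox" if zero_handling == "drop" else "pratt",
        correction=(method == "approx"),
        alternative="two-sided",
        method=method,
    )
    return WilcoxonResult(
        site=site,
        plane=plane,
        n_subjects=n,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        zero_handling=zero_handling,
        alpha=alpha,
    )


def summaries_frame(
    observations: pd.DataFrame, decimals: int | None = None
) -> pd.DataFrame:
    """All available (site, plane, factor_type) summaries as a tidy frame."""
    rows = []
    combos = observations[["site", "plane", "factor_type"]].drop_duplicates()
    for _, c in combos.iterrows():
        s = summarize(observations, c["site"], c["plane"], c["factor_type"])
        rows.append(
            {
                "site": s.site,
                "plane": s.plane,
                "factor_type": s.factor_type,
                "n": s.n_observations,
                "mean": round(s.mean, decimals) if decimals else s.mean,
                "sd": round(s.sd, decimals) if decimals else s.sd,
            }
        )
    return pd.DataFrame(rows)
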