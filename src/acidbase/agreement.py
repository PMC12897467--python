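"""Unmeasured-ion classification and inter-index agreement.

Each of the three indices (AGc, SIG, BEGap) classifies a patient as
unmeasured-anion (UA) acidosis, unmeasured-cation (UC) alkalosis, or normal
relative to its reference: AGc against the 7-17 mmol/L band, SIG and BEGap
against a configurable tolerance around 0. Sign conventions differ: a *high*
AGc or SIG means excess unmeasured anions, while for BEGap it is a *low*
(negative) value.

The central clinical phenomenon quantified here is the dissociation between
numeric correlation and categorical agreement: two indices can be strongly
correlated (|r| > 0.8) yet agree poorly on patient categories (Cohen's
kappa < 0.5) when their centers or scales differ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "UIStatus",
    "ReferenceBands",
    "AgreementReport",
    "classify_ui_status",
    "cohen_kappa",
    "agreement_report",
]

INDICES = ("agc", "sig", "begap")
CATEGORIES = ("UA_acidosis", "normal", "UC_alkalosis")


class UIStatus:
    UA_ACIDOSIS = "UA_acidosis"
    UC_ALKALOSIS = "UC_alkalosis"
    NORMAL = "normal"


@dataclass(frozen=True)
class ReferenceBands:
    """Normality references for the three indices.

    AGc uses an absolute band (default 7-17 mmol/L). SIG and BEGap are
    referenced to 0; since a strict zero would classify essentially every
    patient as abnormal, ``tolerance`` is the half-width of the band treated
    as normal around each center (default 2 mmol/L, configurable).
    """

    agc_normal: tuple[float, float] = (7.0, 17.0)
    sig_center: float = 0.0
    begap_center: float = 0.0
    tolerance: float = 2.0

    def __post_init__(self):
        lo, hi = self.agc_normal
        if not lo < hi:
            raise ValueError("agc_normal must satisfy lower < upper")
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")


def classify_ui_status(value, index: str, bands: ReferenceBands = ReferenceBands()):
    """Classify one value (or an array) by one index's reference band.

    Returns ``UA_acidosis`` / ``normal`` / ``UC_alkalosis``. High AGc or SIG
    and low BEGap indicate unmeasured anions; the opposite tails indicate
    unmeasured cations.
    """
    index = index.lower()
    v = np.asarray(value, dtype=float)
    if index == "agc":
        lo, hi = bands.agc_normal
        out = np.where(v > hi, UIStatus.UA_ACIDOSIS,
                       np.where(v < lo, UIStatus.UC_ALKALOSIS, UIStatus.NORMAL))
    elif index == "sig":
        hi = bands.sig_center + bands.tolerance
        lo = bands.sig_center - bands.tolerance
        out = np.where(v > hi, UIStatus.UA_ACIDOSIS,
                       np.where(v < lo, UIStatus.UC_ALKALOSIS, UIStatus.NORMAL))
    elif index == "begap":
        hi = bands.begap_center + bands.tolerance
        lo = bands.begap_center - bands.tolerance
        out = np.where(v < lo, UIStatus.UA_ACIDOSIS,
                       np.where(v > hi, UIStatus.UC_ALKALOSIS, UIStatus.NORMAL))
    else:
        raise ValueError(f"unknown index {index!r}; expected one of {INDICES}")
    return out.item() if np.isscalar(value) else out


def cohen_kappa(table) -> float:
    """Cohen's kappa from a square contingency table of counts.

    kappa = (p_o - p_e) / (1 - p_e), with chance agreement p_e from the
    marginal products. The degenerate single-category table (p_o = p_e = 1)
    returns 0 by convention: agreement there is indistinguishable from chance.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("contingency table must be square")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    n = t.sum()
    if n == 0:
        raise ValueError("empty contingency table")
    po = np.trace(t) / n
    pe = float(np.sum(t.sum(axis=0) * t.sum(axis=1))) / n**2
    if pe == 1.0:
        return 0.0
    return float((po - pe) / (1.0 - pe))


@dataclass(frozen=True)
class AgreementReport:
    """Pairwise correlation/agreement results among AGc, SIG and BEGap."""

    n: int
    pearson: pd.DataFrame
    kappa: dict[tuple[str, str], float]
    crosstabs: dict[tuple[str, str], pd.DataFrame]
    reclass_counts: dict[str, dict[str, int]]
    bands: ReferenceBands = field(default_factory=ReferenceBands)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pearson": {f"{a}|{b}": (None if pd.isna(v) else round(float(v), 6))
                        for (a, b), v in _pairs_of(self.pearson)},
            "kappa": {f"{a}|{b}": round(float(v), 6) for (a, b), v in self.kappa.items()},
            "crosstabs": {f"{a}|{b}": t.astype(int).values.tolist()
                          for (a, b), t in self.crosstabs.items()},
            "crosstab_categories": list(CATEGORIES),
            "reclass_counts": self.reclass_counts,
            "bands": {
                "agc_normal": list(self.bands.agc_normal),
                "sig_center": self.bands.sig_center,
                "begap_center": self.bands.begap_center,
                "tolerance": self.bands.tolerance,
            },
        }


def _pairs_of(mat: pd.DataFrame):
    for i, a in enumerate(INDICES):
        for b in INDICES[i + 1:]:
            yield (a, b), mat.loc[a, b]


def agreement_report(
    panels: pd.DataFrame, bands: ReferenceBands = ReferenceBands()
) -> AgreementReport:
    """Full pairwise analysis over a panel table with agc/sig/begap columns.

    Computes Pearson correlations (reported missing, with a warning, for a
    constant column), Cohen's kappa and 3x3 cross-classification tables per
    index pair, and — mirroring the clinical question "how often does a
    normal AGc hide an abnormality?" — counts of AGc-normal patients
    reclassified by SIG and BEGap.
    """
    if len(panels) < 2:
        raise ValueError("agreement analysis requires at least 2 patients")
    values = panels[list(INDICES)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pearson = values.corr(method="pearson")
    for col in INDICES:
        if values[col].nunique() <= 1:
            warnings.warn(f"constant column {col!r}: Pearson r undefined", stacklevel=2)
    labels = {idx: classify_ui_status(values[idx].to_numpy(), idx, bands) for idx in INDICES}
    kappa: dict[tuple[str, str], float] = {}
    crosstabs: dict[tuple[str, str], pd.DataFrame] = {}
    for i, a in enumerate(INDICES):
        for b in INDICES[i + 1:]:
            tab = pd.crosstab(
                pd.Categorical(labels[a], categories=CATEGORIES),
                pd.Categorical(labels[b], categories=CATEGORIES),
                dropna=False,
            ).reindex(index=CATEGORIES, columns=CATEGORIES, fill_value=0)
            crosstabs[(a, b)] = tab
            kappa[(a, b)] = cohen_kappa(tab.values)
    agc_normal = labels["agc"] == UIStatus.NORMAL
    reclass = {}
    for other in ("sig", "begap"):
        sub = labels[other][agc_normal]
        reclass[other] = {
            "UA_acidosis": int(np.sum(sub == UIStatus.UA_ACIDOSIS)),
            "UC_alkalosis": int(np.sum(sub == UIStatus.UC_ALKALOSIS)),
            "normal": int(np.sum(sub == UIStatus.NORMAL)),
        }
    return AgreementReport(
        n=len(panels), pearson=pearson, kappa=kappa,
        crosstabs=crosstabs, reclass_counts=reclass, bands=bands,
    )
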