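"""Synthetic ICU admission cohorts with a latent unmeasured-ion burden.

Real ICU blood-gas cohorts of this kind are not publicly deposited, so every
downstream stage of the package runs on generated data. The generator draws
the independent physicochemical variables (electrolytes, albumin, phosphate,
lactate, PaCO2) from marginal distributions whose medians and interquartile
ranges match a published ICU admission cohort, adds a latent net unmeasured
anion load ``xa`` per patient, solves the Stewart charge balance for the
equilibrium pH, derives bicarbonate and standard base excess from it, and
finally overlays analyzer-scale measurement noise.

Because pH is *caused* by ``sid_effective = SIDa - xa`` through the same
effective-SID equation that the strong ion gap inverts, the formula-mode SIG
recomputed from a noise-free record equals ``xa`` exactly, and BEGap tracks
``-xa`` up to the lactate/albumin reference offsets and noise. That
recoverability is the generator's reason to exist: it provides ground truth
for benchmarking the three unmeasured-ion indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .forward import StewartState, UnphysiologicalStateError, solve_ph, implied_chemistry
from .io import COHORT_COLUMNS

__all__ = ["Marginal", "CohortSpec", "SyntheticCohort", "generate_cohort", "make_temporal_split"]

_Z75 = stats.norm.ppf(0.75)  # 0.6745; IQR of a normal is 2*z75*sd


@dataclass(frozen=True)
class Marginal:
    """One variable's target distribution, parametrized by median and quartiles.

    ``family`` is ``normal`` (symmetric analytes), ``lognormal``
    (right-skewed positive analytes: lactate, phosphate, PaCO2) or
    ``skewnorm`` (possibly-negative skewed quantities; ``skew`` is the
    shape parameter). Quantiles are matched exactly under the assumed family.
    """

    family: str
    median: float
    q25: float
    q75: float
    skew: float = 0.0

    def __post_init__(self):
        if self.family not in ("normal", "lognormal", "skewnorm"):
            raise ValueError(f"unknown family {self.family!r}")
        if not self.q25 < self.median < self.q75:
            raise ValueError("need q25 < median < q75")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "normal":
            sd = (self.q75 - self.q25) / (2 * _Z75)
            return rng.normal(self.median, sd, size=n)
        if self.family == "lognormal":
            sigma = math.log(self.q75 / self.q25) / (2 * _Z75)
            return self.median * np.exp(rng.normal(0.0, sigma, size=n))
        p25, p50, p75 = stats.skewnorm.ppf([0.25, 0.5, 0.75], self.skew)
        scale = (self.q75 - self.q25) / (p75 - p25)
        loc = self.median - scale * p50
        return stats.skewnorm.rvs(self.skew, loc=loc, scale=scale, size=n, random_state=rng)


def _default_marginals() -> dict[str, Marginal]:
    # Location/spread targets: published ICU development-cohort medians (IQRs).
    # Chloride is generated as Na minus a sodium-chloride difference so the
    # two covary as they do clinically; the difference spread is chosen so the
    # implied chloride IQR matches its published 100-107 target.
    return {
        "na": Marginal("normal", 138.0, 135.0, 141.0),
        "na_cl_diff": Marginal("normal", 34.0, 32.0, 36.0),
        "k": Marginal("normal", 4.09, 3.63, 4.59),
        "ca": Marginal("normal", 1.17, 1.11, 1.23),
        "mg": Marginal("normal", 0.80, 0.72, 0.90),
        "albumin": Marginal("normal", 31.2, 26.0, 36.4),
        "lactate": Marginal("lognormal", 1.80, 1.20, 2.95),
        "pi": Marginal("lognormal", 1.23, 1.00, 1.58),
        "paco2": Marginal("lognormal", 40.9, 35.0, 47.7),
        # Latent net unmeasured anions: centered at 3.5 mmol/L with the spread
        # of the published SIG distribution (IQR 1.42-6.35), mild right skew,
        # negative values (unmeasured cations) admitted.
        "xa": Marginal("skewnorm", 3.5, 1.28, 6.21, skew=2.0),
    }


def _default_noise_sd() -> dict[str, float]:
    # Analyzer/laboratory imprecision (1 SD, native units), blood-gas
    # analyzer-grade for the gas/electrolyte channel and central-lab-grade
    # for albumin and phosphate.
    return {
        "ph": 0.003,
        "paco2": 0.8,
        "hco3": 0.2,
        "sbe": 0.25,
        "na": 0.7,
        "k": 0.04,
        "cl": 0.8,
        "ca": 0.01,
        "mg": 0.02,
        "lactate": 0.06,
        "albumin": 0.8,
        "pi": 0.04,
    }


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic cohort: size, seed, marginals and noise."""

    n: int
    seed: int = 42
    marginals: dict[str, Marginal] = field(default_factory=_default_marginals)
    noise_sd: dict[str, float] = field(default_factory=_default_noise_sd)
    max_resample_rounds: int = 50

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise_sd entries must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["marginals"] = {k: asdict(m) for k, m in self.marginals.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        d["marginals"] = {k: Marginal(**m) for k, m in d.get("marginals", {}).items()}
        if not d["marginals"]:
            d.pop("marginals")
        return cls(**d)


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated patient table plus per-record ground truth.

    ``records`` uses the canonical cohort CSV columns; ``truth`` is the
    latent net unmeasured anion load (mmol/L) per record, aligned by
    position; ``n_resampled`` counts draws discarded as unphysiological.
    """

    records: pd.DataFrame
    truth: np.ndarray
    spec: CohortSpec
    n_resampled: int = 0

    def __post_init__(self):
        if len(self.records) != len(self.truth):
            raise ValueError("records and truth must have equal length")


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float) for c in COHORT_COLUMNS})


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a cohort per ``spec``; deterministic under the spec's seed.

    Draws that fail physiological validity (non-positive concentrations, no
    charge-balance root in pH [6.5, 7.9], or post-noise values out of range)
    are resampled from the same stream, with a hard cap on rounds.
    """
    if spec.n == 0:
        return SyntheticCohort(_empty_records(), np.empty(0), spec, 0)
    rng = np.random.default_rng(spec.seed)
    m, noise = spec.marginals, spec.noise_sd
    kept: list[dict] = []
    truth: list[float] = []
    discarded = 0
    rounds = 0
    while len(kept) < spec.n:
        if rounds >= spec.max_resample_rounds:
            raise RuntimeError(
                f"exceeded {spec.max_resample_rounds} resampling rounds "
                f"({discarded} unphysiological draws); check marginals"
            )
        rounds += 1
        need = spec.n - len(kept)
        draw = {name: m[name].sample(rng, need) for name in m}
        draw["cl"] = draw["na"] - draw["na_cl_diff"]
        eps = {v: rng.normal(0.0, noise[v], size=need) for v in noise}
        for i in range(need):
            rec = _assemble_record(draw, eps, i)
            if rec is None:
                discarded += 1
            else:
                kept.append(rec)
                truth.append(float(draw["xa"][i]))
    records = pd.DataFrame(kept, columns=COHORT_COLUMNS)
    return SyntheticCohort(records, np.asarray(truth), spec, discarded)


def _assemble_record(draw, eps, i) -> dict | None:
    na, k, ca, mg = draw["na"][i], draw["k"][i], draw["ca"][i], draw["mg"][i]
    cl, lac, alb, pi = draw["cl"][i], draw["lactate"][i], draw["albumin"][i], draw["pi"][i]
    paco2, xa = draw["paco2"][i], draw["xa"][i]
    if min(na, k, ca, mg, cl, lac, pi, paco2) <= 0 or alb < 10.0:
        return None
    sida = (na + k + ca + mg) - (cl + lac)
    try:
        state = StewartState(sid_effective=sida - xa, albumin=alb, pi=pi, paco2=paco2)
        ph = solve_ph(state)
    except (UnphysiologicalStateError, ValueError):
        return None
    derived = implied_chemistry(state, ph)
    rec = {
        "ph": ph + eps["ph"][i],
        "paco2_mmhg": paco2 + eps["paco2"][i],
        "hco3_mmol_l": derived["hco3"] + eps["hco3"][i],
        "sbe_mmol_l": derived["sbe"] + eps["sbe"][i],
        "na": na + eps["na"][i],
        "k": k + eps["k"][i],
        "cl": cl + eps["cl"][i],
        "ca": ca + eps["ca"][i],
        "mg": mg + eps["mg"][i],
        "lactate": lac + eps["lactate"][i],
        "albumin_g_l": alb + eps["albumin"][i],
        "pi_mmol_l": pi + eps["pi"][i],
    }
    if not (6.5 <= rec["ph"] <= 7.9) or rec["hco3_mmol_l"] <= 0:
        return None
    if min(rec["na"], rec["k"], rec["cl"], rec["ca"], rec["mg"], rec["lactate"],
           rec["pi_mmol_l"], rec["paco2_mmhg"]) <= 0 or rec["albumin_g_l"] < 10.0:
        return None
    return rec


def make_temporal_split(
    cohort: SyntheticCohort,
    frac: float,
    seed: int | None = None,
    drift: dict[str, float] | None = None,
) -> tuple[SyntheticCohort, SyntheticCohort]:
    """Partition a cohort into development and validation halves.

    The split emulates a chronological division: generation order stands in
    for admission date and the first ``ceil(frac * n)`` records form the
    development cohort. ``drift`` optionally adds a per-column location shift
    to the validation half (emulating secular drift in later admissions);
    ``seed`` is accepted for interface symmetry with the generator and
    reserved for stochastic drift variants (the default split itself is
    deterministic).
    """
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must be in (0, 1)")
    n = len(cohort.records)
    n_dev = math.ceil(frac * n)
    dev_df = cohort.records.iloc[:n_dev].reset_index(drop=True)
    val_df = cohort.records.iloc[n_dev:].reset_index(drop=True)
    if drift:
        val_df = val_df.copy()
        for col, delta in drift.items():
            if col not in val_df.columns:
                raise ValueError(f"drift column {col!r} not in cohort")
            val_df[col] = val_df[col] + delta
    dev = SyntheticCohort(dev_df, cohort.truth[:n_dev], cohort.spec, 0)
    val = SyntheticCohort(val_df, cohort.truth[n_dev:], cohort.spec, 0)
    return dev, val
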