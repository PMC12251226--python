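"""Hill-equation pharmacology: drug + concentration -> fractional channel block.

Drug effects on IKr and ICaL are modelled as simple pore block.  For a drug
concentration ``D`` and channel-specific Hill parameters (half-inhibitory
concentration ``IC50``, Hill coefficient ``h``), the current carried in the
presence of drug is

    I(D) = I0 / (1 + (D / IC50)^h)

so the *fraction remaining* is ``1 / (1 + (D/IC50)^h)`` and the block
fraction is its complement.  IC50 values reported only as a lower bound
("> X": no measurable inhibition up to the highest tested concentration)
are treated as *censored*: the drug is modelled as fully selective, with
zero block on that channel at the study concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from apdbench.pacing import BlockSpec

__all__ = [
    "HillParameters", "DrugEntry", "DrugCondition", "HillFit",
    "fraction_remaining", "block_fraction", "drug_block", "fit_hill",
    "CensoredParameterError",
]

Dataset = Literal["CiPA", "Pharm"]


class CensoredParameterError(ValueError):
    """Raised when Eq-style evaluation is attempted on a censored IC50."""


@dataclass(frozen=True)
class HillParameters:
    """IC50 (uM) and Hill coefficient; ``censored_above`` marks '>X' entries."""

    ic50: float | None
    h: float | None = None
    censored_above: float | None = None

    def __post_init__(self):
        if self.censored_above is not None:
            if self.censored_above <= 0:
                raise ValueError("censored bound must be positive")
            return
        if self.ic50 is None or self.ic50 <= 0:
            raise ValueError("ic50 must be positive (or censored)")
        if self.h is None or self.h <= 0:
            raise ValueError("Hill coefficient must be positive")

    @property
    def censored(self) -> bool:
        return self.censored_above is not None


@dataclass(frozen=True)
class DrugEntry:
    """One drug's IKr/ICaL Hill parameters under one patch-clamp dataset."""

    drug: str
    dataset: Dataset
    ikr: HillParameters
    ical: HillParameters


@dataclass(frozen=True)
class DrugCondition:
    """A drug at one bath concentration."""

    drug: str
    concentration: float  # uM
    concentration_kind: Literal["nominal", "measured"] = "nominal"

    def __post_init__(self):
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")


def fraction_remaining(d: float, hill: HillParameters) -> float:
    """Fraction of current remaining at concentration ``d`` (uM).

    Raises :class:`CensoredParameterError` for censored parameters — use
    :func:`drug_block`, which applies the selectivity rule instead.
    """
    if hill.censored:
        raise CensoredParameterError(
            "IC50 is a censored bound ('>X'); use drug_block, which treats the "
            "drug as selective (zero block on this channel)"
        )
    if d < 0:
        raise ValueError("concentration must be non-negative")
    if d == 0.0:
        return 1.0
    return float(1.0 / (1.0 + (d / hill.ic50) ** hill.h))


def block_fraction(d: float, hill: HillParameters) -> float:
    """Block fraction ``1 - fraction_remaining``; 0 for censored entries."""
    if hill.censored:
        return 0.0
    return 1.0 - fraction_remaining(d, hill)


def drug_block(
    cond: DrugCondition,
    dataset: Dataset,
    table: Mapping[tuple[str, str], DrugEntry] | None = None,
) -> BlockSpec:
    """IKr/ICaL block fractions for one drug condition.

    ``table`` maps ``(drug, dataset)`` to :class:`DrugEntry`; by default the
    packaged study table is used.  Censored IC50 entries give exactly zero
    block on that channel (selective-inhibitor modelling).
    """
    if table is None:
        from apdbench.datasets import load_study_tables

        table = load_study_tables().table3
    key = (cond.drug, dataset)
    if key not in table:
        raise KeyError(f"no Hill parameters for drug {cond.drug!r} in dataset {dataset!r}")
    entry = table[key]
    return BlockSpec(
        ikr_block=block_fraction(cond.concentration, entry.ikr),
        ical_block=block_fraction(cond.concentration, entry.ical),
    )


@dataclass(frozen=True)
class HillFit:
    """Result of a least-squares Hill fit."""

    params: HillParameters
    residual_norm: float
    warnings: tuple[str, ...] = ()


def fit_hill(doses: Sequence[float], fractions_remaining: Sequence[float]) -> HillFit:
    """Least-squares fit of the Hill equation in log-dose space.

    Needs at least three dose levels.  Non-monotone data (beyond a 5 %
    tolerance) or flat dose-response data are flagged in ``warnings``
    rather than raising.
    """
    from scipy.optimize import least_squares

    d = np.asarray(doses, dtype=float)
    f = np.asarray(fractions_remaining, dtype=float)
    if d.size != f.size:
        raise ValueError("doses and fractions must have equal length")
    if d.size < 3:
        raise ValueError("need >= 3 dose levels")
    if np.any(d <= 0):
        raise ValueError("doses must be positive")

    order = np.argsort(d)
    d, f = d[order], f[order]
    warnings: list[str] = []
    if float(np.ptp(f)) < 0.05:
        warnings.append("non-identifiable: dose-response is flat")
    # running max of fractions should not rise along increasing dose
    rise = float(np.max(f - np.minimum.accumulate(f)))
    if rise > 0.05:
        warnings.append("non-monotone dose-response beyond noise tolerance")

    logd = np.log(d)
    # initial IC50: dose closest to half-block (clipped into the tested range)
    i0 = int(np.argmin(np.abs(f - 0.5)))
    x0 = np.array([logd[i0], 0.0])  # [log ic50, log h]

    def resid(x):
        return 1.0 / (1.0 + np.exp(np.exp(x[1]) * (logd - x[0]))) - f

    sol = least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    ic50 = float(np.exp(sol.x[0]))
    h = float(np.exp(sol.x[1]))
    return HillFit(
        params=HillParameters(ic50=ic50, h=h),
        residual_norm=float(np.linalg.norm(sol.fun)),
        warnings=tuple(warnings),
    )
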