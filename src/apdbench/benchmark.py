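"""Model benchmarking: 2-D inhibition maps, study predictions, the error
measure E, and the cubic experimental response surface.

The central quantity is the drug-induced change in APD90 from baseline,
ΔAPD90, as a function of the fractional block of IKr and ICaL.  Models
are scored against the trabecula data with

    E = Σ_k | ΔAPD90,sim,k − mean ΔAPD90,exp,k | / σM,exp,k

summed over the study's drug-concentration conditions k, where σM is the
experimental standard error of the mean — so each condition contributes
its prediction error in multiples of the experimental SEM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from apdbench.pacing import BlockSpec, simulate_delta_apd90
from apdbench.pharmacology import DrugCondition, drug_block

__all__ = [
    "ExperimentalRecord", "DeltaAPDMap", "ErrorReport", "SurfaceFit",
    "compute_map", "zero_contour", "zero_line_slope", "predict_study",
    "error_measure", "fit_cubic_surface", "evaluate_surface",
    "ConditionMismatchError", "ModelExcludedError",
]

#: Experimental bath concentrations (K+/Na+/Ca2+, mM) used when comparing
#: simulations quantitatively with the trabecula recordings.
EXPERIMENTAL_CONCENTRATIONS = (4.0, 148.35, 1.8)

#: Bivariate cubic basis exponents (i, j) for x^i y^j, i + j <= 3.
CUBIC_EXPONENTS = ((0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2),
                   (3, 0), (2, 1), (1, 2), (0, 3))


class ConditionMismatchError(ValueError):
    """Predictions and experimental records do not cover the same conditions."""


class ModelExcludedError(ValueError):
    """Model is excluded from quantitative comparison (non-physiological AP
    under experimental bath concentrations)."""


@dataclass(frozen=True)
class ExperimentalRecord:
    """One drug condition's trabecula summary (mean ± SEM over trabeculae)."""

    drug: str
    concentration: float          # uM (nominal)
    mean_delta_apd90: float       # ms
    sem: float                    # ms (σM)
    n_trabeculae: int
    mean_baseline_apd90: float    # ms
    baseline_sd: float            # ms

    def __post_init__(self):
        if self.sem <= 0:
            raise ValueError("sem must be positive")
        if self.n_trabeculae < 1:
            raise ValueError("n_trabeculae must be >= 1")

    @property
    def condition(self) -> tuple[str, float]:
        return (self.drug, self.concentration)


@dataclass(frozen=True)
class DeltaAPDMap:
    """Grid of ΔAPD90 (ms) over (IKr block, ICaL block) fractions.

    ``values[i, j]`` corresponds to ``ikr_axis[i]``, ``ical_axis[j]``.
    Cells where the blocked AP failed to repolarise are NaN and flagged in
    ``no_repolarisation``.
    """

    ikr_axis: np.ndarray
    ical_axis: np.ndarray
    values: np.ndarray
    model: str
    concentration_mode: Literal["default", "experimental"] = "default"

    def __post_init__(self):
        if self.values.shape != (self.ikr_axis.size, self.ical_axis.size):
            raise ValueError("values shape must match the axes")
        v00 = self.values[0, 0]
        if self.ikr_axis[0] == 0 and self.ical_axis[0] == 0 and v00 != 0.0:
            raise ValueError("map value at (0, 0) must be 0 ms")

    @property
    def no_repolarisation(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.values,
            index=pd.Index(self.ikr_axis, name="ikr_block"),
            columns=pd.Index(self.ical_axis, name="ical_block"),
        )


@dataclass(frozen=True)
class ErrorReport:
    """Error measure E with per-condition and per-drug decomposition."""

    total_e: float
    per_condition: tuple  # of (condition, sim, exp_mean, sem, |z|)
    per_drug: Mapping[str, float]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(d, c, s, m, sem, z) for ((d, c), s, m, sem, z) in self.per_condition],
            columns=["drug", "concentration_um", "sim_ms", "exp_mean_ms",
                     "sem_ms", "abs_z"],
        )


@dataclass(frozen=True)
class SurfaceFit:
    """Bivariate cubic surface Σ c_ij x^i y^j (x = IKr block, y = ICaL block)."""

    coefficients: np.ndarray           # 10 values, ordered per CUBIC_EXPONENTS
    dataset: str | None = None
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        c = np.asarray(self.coefficients, dtype=float)
        if c.shape != (10,):
            raise ValueError("a bivariate cubic has exactly 10 coefficients")
        object.__setattr__(self, "coefficients", c)

    def __call__(self, x, y):
        return evaluate_surface(self, x, y)


def _cubic_design(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.column_stack([x ** i * y ** j for i, j in CUBIC_EXPONENTS])


def evaluate_surface(fit: SurfaceFit, ikr, ical):
    x = np.asarray(ikr, dtype=float)
    y = np.asarray(ical, dtype=float)
    out = _cubic_design(np.ravel(x), np.ravel(y)) @ fit.coefficients
    return float(out[0]) if np.isscalar(ikr) and np.isscalar(ical) else out.reshape(x.shape)


def fit_cubic_surface(
    points: Sequence[tuple[float, float, float]],
    dataset: str | None = None,
    weights: Sequence[float] | None = None,
) -> SurfaceFit:
    """Least-squares bivariate cubic through (ikr, ical, ΔAPD90) points.

    Unweighted ordinary least squares by default; pass ``weights`` (e.g.
    1/SEM²) to weight the fit.  Requires at least 10 points in general
    position; a rank-deficient design raises with the deficiency named.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (ikr, ical, delta_apd90) triples")
    if pts.shape[0] < 10:
        raise ValueError(
            f"need >= 10 points to determine 10 cubic coefficients, got {pts.shape[0]}"
        )
    X = _cubic_design(pts[:, 0], pts[:, 1])
    z = pts[:, 2]
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        X = X * w[:, None]
        z = z * w
    rank = np.linalg.matrix_rank(X)
    if rank < 10:
        raise np.linalg.LinAlgError(
            f"cubic design matrix is rank deficient (rank {rank} < 10): "
            "points do not span the bivariate cubic basis"
        )
    coef, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = _cubic_design(pts[:, 0], pts[:, 1]) @ coef - pts[:, 2]
    return SurfaceFit(coefficients=coef, dataset=dataset, residuals=resid)


def _resolve_model(model, concentration_mode: str):
    from apdbench.models import get_model, set_external_concentrations

    m = get_model(model) if isinstance(model, str) else model.copy()
    if concentration_mode == "experimental":
        m = set_external_concentrations(m, *EXPERIMENTAL_CONCENTRATIONS)
    elif concentration_mode != "default":
        raise ValueError(f"unknown concentration mode {concentration_mode!r}")
    return m


def compute_map(
    model,
    resolution: int = 101,
    concentration_mode: Literal["default", "experimental"] = "default",
    n_paces: int = 1500,
    dt_scale: float = 1.0,
) -> DeltaAPDMap:
    """ΔAPD90 over a ``resolution x resolution`` grid of block fractions.

    The default-resolution study grid is 101 x 101 (10,201 simulations);
    reduced resolutions share grid values with the full map at common
    block fractions because each cell is an independent simulation of the
    same protocol.  No-repolarisation cells become NaN flags.
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    m = _resolve_model(model, concentration_mode)
    axis = np.linspace(0.0, 1.0, resolution)
    values = np.empty((resolution, resolution))
    for i, ikr in enumerate(axis):
        for j, ical in enumerate(axis):
            values[i, j] = simulate_delta_apd90(
                m, BlockSpec(ikr_block=ikr, ical_block=ical),
                n_paces=n_paces, dt_scale=dt_scale,
            )
    return DeltaAPDMap(ikr_axis=axis, ical_axis=axis, values=values,
                       model=m.name, concentration_mode=concentration_mode)


def zero_contour(map_: DeltaAPDMap, tol: float = 1.0) -> set[tuple[int, int]]:
    """Grid cells with |ΔAPD90| <= tol ms (the "0 ms line" pixels).

    NaN (no-repolarisation) cells are never part of the contour.
    """
    ok = np.abs(map_.values) <= tol
    ok &= ~map_.no_repolarisation
    return {(int(i), int(j)) for i, j in zip(*np.nonzero(ok))}


def zero_line_slope(map_: DeltaAPDMap, tol: float = 1.0,
                    interpolate: bool = False) -> float:
    """Least-squares slope (ICaL block per IKr block) of the 0-ms line.

    With ``interpolate=True`` the line is located by the linearly
    interpolated sign change of ΔAPD90 along ICaL within each IKr row —
    robust on coarse grids where few cells fall inside the |Δ| <= tol
    pixel band.
    """
    if interpolate:
        pts = []
        for i, ikr in enumerate(map_.ikr_axis):
            row = map_.values[i]
            ok = ~np.isnan(row)
            v = row[ok]
            c = map_.ical_axis[ok]
            sign_change = np.nonzero(np.diff(np.sign(v)) != 0)[0]
            if sign_change.size == 0:
                continue
            j = sign_change[0]
            frac = v[j] / (v[j] - v[j + 1])
            pts.append((ikr, c[j] + frac * (c[j + 1] - c[j])))
        if len(pts) < 2:
            raise ValueError("0-ms line crosses fewer than 2 rows")
        x, y = np.array(pts).T
    else:
        cells = zero_contour(map_, tol)
        if len(cells) < 2:
            raise ValueError("0-ms contour has fewer than 2 cells; cannot fit a slope")
        x = np.array([map_.ikr_axis[i] for i, _ in cells])
        y = np.array([map_.ical_axis[j] for _, j in cells])
    if np.ptp(x) == 0:
        raise ValueError("0-ms contour is vertical (no IKr spread)")
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)


def predict_study(
    model,
    dataset: Literal["CiPA", "Pharm"],
    conditions: Sequence[DrugCondition],
    n_paces: int = 1500,
    dt_scale: float = 1.0,
    table=None,
) -> dict[tuple[str, float], float]:
    """Per-condition ΔAPD90 predictions at study concentrations.

    External concentrations are set to the experimental bath (4 / 148.35 /
    1.8 mM K+/Na+/Ca2+).  The TNNP model is explicitly excluded: it does
    not produce a physiological AP in this configuration.
    """
    name = model if isinstance(model, str) else model.name
    if name == "TNNP":
        raise ModelExcludedError(
            "TNNP is excluded from quantitative comparison: it does not predict "
            "a physiological AP at experimental bath concentrations"
        )
    m = _resolve_model(model, "experimental")
    cycle_length = 1000.0
    out: dict[tuple[str, float], float] = {}
    for cond in conditions:
        block = drug_block(cond, dataset, table=table)
        delta = simulate_delta_apd90(m, block, n_paces=n_paces,
                                     dt_scale=dt_scale, cycle_length=cycle_length)
        if np.isnan(delta):
            # repolarisation failure: APD90 >= the pacing cycle, so the
            # prediction is scored at the cycle-length ceiling — a
            # conservative lower bound on the model's error
            from apdbench.pacing import _steady_apd90

            _, baseline = _steady_apd90(m, n_paces, cycle_length, dt_scale)
            delta = cycle_length - baseline
        out[(cond.drug, cond.concentration)] = float(delta)
    return out


def error_measure(
    predictions: Mapping[tuple[str, float], float],
    records: Iterable[ExperimentalRecord],
) -> ErrorReport:
    """The error measure E over matched (drug, concentration) conditions.

    Per condition k: |z_k| = |sim_k − exp_mean_k| / SEM_k; E = Σ_k |z_k|.
    Raises :class:`ConditionMismatchError` listing any condition present
    on one side only.
    """
    records = list(records)
    rec_keys = {r.condition for r in records}
    pred_keys = set(predictions)
    if rec_keys != pred_keys:
        missing = sorted(rec_keys - pred_keys)
        extra = sorted(pred_keys - rec_keys)
        raise ConditionMismatchError(
            f"unmatched conditions; missing predictions: {missing}; "
            f"predictions without records: {extra}"
        )
    per_condition = []
    per_drug: dict[str, float] = {}
    total = 0.0
    for r in sorted(records, key=lambda r: r.condition):
        sim = float(predictions[r.condition])
        z = abs(sim - r.mean_delta_apd90) / r.sem
        per_condition.append((r.condition, sim, r.mean_delta_apd90, r.sem, z))
        per_drug[r.drug] = per_drug.get(r.drug, 0.0) + z
        total += z
    return ErrorReport(total_e=total, per_condition=tuple(per_condition),
                       per_drug=per_drug)
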