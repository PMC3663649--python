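"""Chemical-shift-perturbation (CSP) titration analysis.

In the fast-exchange regime a resonance sits at the population-weighted
average of its free and bound positions, so the combined CSP of residue
``r`` at titration point ``i`` follows

    csp_ri = csp_max_r * [PL]_i / P0

with the complex concentration ``[PL]`` from the depletion-corrected 1:1
mass balance (:func:`nucbind.equilibria.solve_1to1_complex`).  The model
here fits one shared dissociation constant across all residues together
with one saturation amplitude ``csp_max_r`` per residue — the standard
global-fit strategy for weak binders, where single curves are nearly
linear and only the ensemble constrains K_D.

The fit is separable: for a fixed K_D the amplitudes are linear
least-squares, so the K_D likelihood profile is computed exactly by
variable projection and the optimum polished by Levenberg–Marquardt.
Confidence intervals are profile-likelihood bounds at the F(1, n-p)
threshold; an unsaturated titration yields an open upper bound reported
as ``inf``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .equilibria import solve_1to1_complex

__all__ = [
    "ShiftRecord",
    "CspCurve",
    "IsothermFit",
    "compute_csp",
    "csp_threshold",
    "truncate_series",
    "curves_from_peaklists",
    "CspTitrationModel",
    "fit_isotherm_global",
    "confidence_interval_95",
]

#: conventional combined-CSP weights for the indirect nucleus
X_WEIGHT_15N = 0.2
X_WEIGHT_13C = 0.3


@dataclass(frozen=True)
class ShiftRecord:
    """One assigned resonance position at one titration point."""

    residue_id: int
    residue_name: str
    shift_h: float  # 1H ppm
    shift_x: float  # 15N or 13C ppm
    titration_index: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.shift_h) and np.isfinite(self.shift_x)):
            raise ValueError("chemical shifts must be finite")
        if self.titration_index < 0:
            raise ValueError("titration_index must be >= 0 (0 = free state)")


@dataclass
class CspCurve:
    """Combined CSP of one residue along a titration schedule."""

    residue_id: int
    csp: np.ndarray  # ppm, first point (free state) is 0
    ligand_total: np.ndarray  # mol/L, same length
    receptor_total: float  # mol/L

    def __post_init__(self) -> None:
        self.csp = np.asarray(self.csp, dtype=float)
        self.ligand_total = np.asarray(self.ligand_total, dtype=float)
        if self.csp.shape != self.ligand_total.shape:
            raise ValueError("csp and ligand_total must have the same length")
        if np.any(self.csp < 0):
            raise ValueError("csp values must be >= 0")
        if self.csp[0] != 0.0:
            raise ValueError("first (free-state) point must have csp = 0")
        if self.receptor_total <= 0:
            raise ValueError("receptor_total must be > 0")


@dataclass
class IsothermFit:
    """Result of a global 1:1 fast-exchange isotherm fit."""

    kd: float  # mol/L
    csp_max: dict[int, float]  # ppm per residue
    ci95: tuple[float, float]  # mol/L; upper may be inf (unsaturated)
    rmsd_residuals: float  # ppm
    n_points_used: int
    receptor_total: float = field(repr=False, default=float("nan"))
    _model: "CspTitrationModel | None" = field(repr=False, default=None, compare=False)

    def predict(self, residue_id: int, ligand_total) -> np.ndarray:
        """Model CSP curve for one residue at the given ligand totals."""
        pl = solve_1to1_complex(self.receptor_total, np.asarray(ligand_total, float), self.kd)
        return self.csp_max[residue_id] * pl / self.receptor_total

    def summary(self) -> str:
        lines = [
            "Global 1:1 fast-exchange isotherm fit",
            "=" * 45,
            f"K_D               : {self.kd:.4g} M",
            f"95% CI            : [{self.ci95[0]:.4g}, "
            + (f"{self.ci95[1]:.4g}] M" if np.isfinite(self.ci95[1]) else "inf) M (unsaturated)"),
            f"residual RMSD     : {self.rmsd_residuals:.4g} ppm",
            f"points used       : {self.n_points_used}",
            "per-residue csp_max (ppm):",
        ]
        for rid, cmax in sorted(self.csp_max.items()):
            lines.append(f"  residue {rid:4d}   : {cmax:.4f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed points and fitted curves per residue (lazy matplotlib)."""
        import matplotlib.pyplot as plt

        if self._model is None:
            raise ValueError("fit carries no data to plot")
        if ax is None:
            _, ax = plt.subplots()
        for curve in self._model.curves:
            grid = np.linspace(0, curve.ligand_total.max(), 200)
            ax.plot(curve.ligand_total * 1e3, curve.csp, "o", label=f"res {curve.residue_id}")
            ax.plot(grid * 1e3, self.predict(curve.residue_id, grid), "-", color="0.4")
        ax.set_xlabel("ligand total (mM)")
        ax.set_ylabel("combined CSP (ppm)")
        ax.legend(fontsize="small")
        return ax


def compute_csp(free: ShiftRecord, bound_point: ShiftRecord, x_weight: float = X_WEIGHT_15N) -> float:
    """Combined CSP between the free and a bound-point record.

    ``sqrt(d_H^2 + (w * d_X)^2)`` with the conventional amide weight
    ``w = 0.2`` for 15N (use 0.3 for 13C).
    """
    if x_weight <= 0:
        raise ValueError("x_weight must be > 0")
    if free.residue_id != bound_point.residue_id:
        raise ValueError(
            f"residue mismatch: {free.residue_id} vs {bound_point.residue_id}"
        )
    d_h = bound_point.shift_h - free.shift_h
    d_x = bound_point.shift_x - free.shift_x
    return math.hypot(d_h, x_weight * d_x)


def csp_threshold(
    csps,
    trim_fraction: float = 0.10,
    n_sigma: float = 2.0,
    sigma_on_trimmed: bool = True,
) -> float:
    """Significance threshold: trimmed mean + ``n_sigma`` standard deviations.

    ``trim_fraction`` is removed from *each* tail of the sorted values.  By
    default the standard deviation (sample, ddof=1) is taken over the same
    trimmed set; ``sigma_on_trimmed=False`` uses the full set instead.
    """
    values = np.sort(np.asarray(csps, dtype=float))
    if values.size < 3:
        raise ValueError("need at least 3 CSP values to set a threshold")
    if not (0 <= trim_fraction < 0.5):
        raise ValueError("trim_fraction must be in [0, 0.5)")
    k = int(trim_fraction * values.size)
    trimmed = values[k : values.size - k] if k else values
    sigma_set = trimmed if sigma_on_trimmed else values
    sigma = float(np.std(sigma_set, ddof=1)) if sigma_set.size > 1 else 0.0
    return float(np.mean(trimmed)) + n_sigma * sigma


def truncate_series(curves: list[CspCurve], max_ligand: float) -> list[CspCurve]:
    """Restrict every curve to titration points with ligand_total <= max_ligand.

    The free (zero-ligand) point always survives.  Raises if fewer than 3
    points remain.
    """
    if max_ligand <= 0:
        raise ValueError("max_ligand must be > 0")
    out = []
    for c in curves:
        keep = c.ligand_total <= max_ligand
        keep[0] = True
        if keep.sum() < 3:
            raise ValueError(
                f"truncation at {max_ligand} M leaves fewer than 3 points"
            )
        out.append(CspCurve(c.residue_id, c.csp[keep], c.ligand_total[keep], c.receptor_total))
    return out


def curves_from_peaklists(
    peaklists: list[list[ShiftRecord]],
    ligand_totals,
    receptor_total: float,
    x_weight: float = X_WEIGHT_15N,
) -> list[CspCurve]:
    """Derive per-residue CSP curves from per-point peak lists.

    ``peaklists[0]`` is the free state; curves are built for residues
    present in every list.
    """
    ligand_totals = np.asarray(ligand_totals, dtype=float)
    if len(peaklists) != ligand_totals.size:
        raise ValueError("one peak list per titration point required")
    by_point = [{r.residue_id: r for r in pl} for pl in peaklists]
    common = set(by_point[0])
    for d in by_point[1:]:
        common &= set(d)
    curves = []
    for rid in sorted(common):
        free = by_point[0][rid]
        csp = np.array([compute_csp(free, d[rid], x_weight) for d in by_point])
        csp[0] = 0.0
        curves.append(CspCurve(rid, csp, ligand_totals, receptor_total))
    return curves


class CspTitrationModel:
    """Global fast-exchange isotherm model over a set of CSP curves.

    All curves share one titration schedule and one receptor concentration;
    the fit estimates a single K_D plus one ``csp_max`` per residue.
    """

    #: K_D search window for the multi-start grid, mol/L
    KD_BOUNDS = (1e-8, 1e2)

    def __init__(self, curves: list[CspCurve], receptor_total: float | None = None):
        if not curves:
            raise ValueError("need at least one CSP curve")
        schedule = curves[0].ligand_total
        for c in curves[1:]:
            if not np.array_equal(c.ligand_total, schedule):
                raise ValueError("all curves must share one titration schedule")
        if np.any(np.diff(schedule) < 0):
            raise ValueError("ligand_total schedule must be non-decreasing")
        if schedule.size < 4:
            raise ValueError(
                f"under-determined: need >= 4 titration points, got {schedule.size}"
            )
        self.curves = curves
        self.schedule = schedule
        self.receptor_total = float(receptor_total if receptor_total is not None else curves[0].receptor_total)
        self._obs = np.stack([c.csp for c in curves])  # (R, T)
        if not np.any(self._obs > 0):
            raise ValueError("no binding signal: all CSP values are zero")

    @classmethod
    def from_dataframe(cls, df, receptor_total: float) -> "CspTitrationModel":
        """Build from a tidy table with columns residue_id, ligand_total_M, csp_ppm."""
        curves = []
        for rid, grp in df.groupby("residue_id"):
            grp = grp.sort_values("ligand_total_M")
            curves.append(
                CspCurve(int(rid), grp["csp_ppm"].to_numpy(), grp["ligand_total_M"].to_numpy(), receptor_total)
            )
        return cls(curves, receptor_total)

    # -- variable projection ------------------------------------------------
    def _bound_fraction(self, kd: float) -> np.ndarray:
        return solve_1to1_complex(self.receptor_total, self.schedule, kd) / self.receptor_total

    def _amplitudes(self, kd: float) -> np.ndarray:
        f = self._bound_fraction(kd)
        denom = float(f @ f)
        if denom == 0.0:
            return np.zeros(self._obs.shape[0])
        return self._obs @ f / denom

    def profile_rss(self, kd: float) -> float:
        """Residual sum of squares with amplitudes projected out at this K_D."""
        f = self._bound_fraction(kd)
        a = self._amplitudes(kd)
        resid = self._obs - np.outer(a, f)
        return float(np.sum(resid * resid))

    def fit(self, n_grid: int = 61) -> IsothermFit:
        """Multi-start variable-projection fit with LM polish and profile CI."""
        lo, hi = self.KD_BOUNDS
        grid = np.logspace(math.log10(lo), math.log10(hi), n_grid)
        rss = np.array([self.profile_rss(k) for k in grid])
        i = int(np.argmin(rss))
        bracket = (grid[max(i - 1, 0)], grid[min(i + 1, n_grid - 1)])
        res = optimize.minimize_scalar(
            lambda lg: self.profile_rss(10.0**lg),
            bounds=(math.log10(bracket[0]), math.log10(bracket[1])),
            method="bounded",
            options={"xatol": 1e-10},
        )
        kd0 = 10.0**res.x
        # LM polish on (log10 kd, amplitudes): quadratic convergence on
        # near-zero-residual problems, recovers noiseless truth to ~eps
        a0 = self._amplitudes(kd0)

        def residuals(theta):
            f = self._bound_fraction(10.0 ** theta[0])
            return (self._obs - np.outer(theta[1:], f)).ravel()

        sol = optimize.least_squares(
            residuals,
            np.concatenate([[math.log10(kd0)], a0]),
            method="lm",
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
        )
        kd = 10.0 ** sol.x[0]
        amps = self._amplitudes(kd)
        rss_min = self.profile_rss(kd)
        n = self._obs.size
        p = 1 + len(self.curves)
        rmsd = math.sqrt(rss_min / n)
        ci = self._profile_ci(kd, rss_min, n, p)
        fit = IsothermFit(
            kd=kd,
            csp_max={c.residue_id: float(a) for c, a in zip(self.curves, amps)},
            ci95=ci,
            rmsd_residuals=rmsd,
            n_points_used=n,
            receptor_total=self.receptor_total,
            _model=self,
        )
        return fit

    def _profile_ci(self, kd: float, rss_min: float, n: int, p: int) -> tuple[float, float]:
        """Profile-likelihood 95% interval for K_D (F-test threshold)."""
        dof = n - p
        if dof <= 0 or rss_min == 0.0:
            return (kd, kd)  # noiseless/saturated: interval collapses
        thr = rss_min * (1.0 + stats.f.ppf(0.95, 1, dof) / dof)

        def g(lg):
            return self.profile_rss(10.0**lg) - thr

        lg_kd = math.log10(kd)
        lo_bound, hi_bound = math.log10(self.KD_BOUNDS[0]), math.log10(self.KD_BOUNDS[1])
        # lower bound
        lower = self.KD_BOUNDS[0]
        lg = lg_kd
        step = 0.25
        while lg - step >= lo_bound and g(lg - step) < 0:
            lg -= step
        if lg - step >= lo_bound:
            lower = 10.0 ** optimize.brentq(g, lg - step, lg_kd)
        # upper bound; open-ended when the titration never saturates
        upper = math.inf
        lg = lg_kd
        while lg + step <= hi_bound and g(lg + step) < 0:
            lg += step
        if lg + step <= hi_bound:
            upper = 10.0 ** optimize.brentq(g, lg_kd, lg + step)
        else:
            warnings.warn(
                "upper K_D bound is open-ended (titration does not saturate)",
                stacklevel=3,
            )
        return (lower, upper)


def fit_isotherm_global(
    curves: list[CspCurve],
    schedule=None,
    receptor_total: float | None = None,
) -> IsothermFit:
    """Fit one shared K_D and per-residue csp_max to a set of CSP curves.

    ``schedule``/``receptor_total`` default to the values the curves carry.
    """
    if schedule is not None:
        schedule = np.asarray(schedule, dtype=float)
        for c in curves:
            if not np.array_equal(c.ligand_total, schedule):
                raise ValueError("explicit schedule disagrees with curves")
    return CspTitrationModel(curves, receptor_total).fit()


def confidence_interval_95(fit: IsothermFit, curves: list[CspCurve], schedule=None) -> tuple[float, float]:
    """Profile-likelihood 95% interval for a converged isotherm fit."""
    model = CspTitrationModel(curves, fit.receptor_total)
    rss_min = model.profile_rss(fit.kd)
    n = model._obs.size
    return model._profile_ci(fit.kd, rss_min, n, 1 + len(curves))
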