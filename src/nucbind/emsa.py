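"""Gel-shift (EMSA) densitometry fitting under the two-equivalent-site model.

Each lane of a nucleosome titration resolves three bands — free particle,
one reader bound (+1) and two readers bound (+2).  Ethidium stains the
same wrapped DNA in every species, so integrated band densities are
proportional to species amounts and lane-normalised densities estimate
the species fractions directly (an optional per-band response vector can
correct unequal staining).  The fractions at every titration step are
binomial in the per-site occupancy from the shared mass balance
(:func:`nucbind.equilibria.solve_two_site`), leaving the microscopic K_D
as the single fitted parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .equilibria import solve_two_site

__all__ = ["LaneDensities", "EmsaFitResult", "lane_fractions", "EmsaModel", "fit_emsa"]


@dataclass(frozen=True)
class LaneDensities:
    """Integrated band densities of one gel lane."""

    equivalents: float  # ligand:receptor molar ratio
    density_free: float
    density_b1: float
    density_b2: float
    receptor_total: float  # mol/L
    lane_id: str = ""

    def __post_init__(self) -> None:
        if self.equivalents < 0:
            raise ValueError("equivalents must be >= 0")
        d = (self.density_free, self.density_b1, self.density_b2)
        if any(x < 0 for x in d):
            raise ValueError("band densities must be >= 0")
        if sum(d) <= 0:
            raise ValueError("lane has zero total density")
        if self.receptor_total <= 0:
            raise ValueError("receptor_total must be > 0")


@dataclass
class EmsaFitResult:
    """2:1 binding-model fit of a lane series."""

    kd_micro: float  # mol/L
    ci95: tuple[float, float]
    per_lane_predicted: list[tuple[float, float, float]]
    rss: float
    _model: "EmsaModel | None" = field(repr=False, default=None, compare=False)

    def summary(self) -> str:
        lines = [
            "EMSA 2:1 binding-model fit (two equivalent sites)",
            "=" * 50,
            f"microscopic K_D : {self.kd_micro * 1e6:.3g} uM",
            f"95% CI          : [{self.ci95[0] * 1e6:.3g}, "
            + (f"{self.ci95[1] * 1e6:.3g}] uM" if np.isfinite(self.ci95[1]) else "inf) uM"),
            f"RSS             : {self.rss:.5g}",
            "lane   eq    f0_pred f1_pred f2_pred",
        ]
        for lane, pred in zip(self._model.lanes if self._model else [], self.per_lane_predicted):
            lines.append(
                f"{lane.lane_id or '-':5s} {lane.equivalents:4.2f}  "
                f"{pred[0]:.3f}  {pred[1]:.3f}  {pred[2]:.3f}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed (points) and fitted (lines) species fractions vs equivalents."""
        import matplotlib.pyplot as plt

        if self._model is None:
            raise ValueError("result carries no data to plot")
        if ax is None:
            _, ax = plt.subplots()
        eq = np.array([l.equivalents for l in self._model.lanes])
        obs = np.array([lane_fractions(l) for l in self._model.lanes])
        n0 = self._model.lanes[0].receptor_total
        grid = np.linspace(0, eq.max(), 200)
        pred = np.array([solve_two_site(n0, e * n0, self.kd_micro).species_fractions for e in grid])
        for k, (label, color) in enumerate(
            [("free", "tab:blue"), ("+1", "tab:green"), ("+2", "tab:red")]
        ):
            ax.plot(eq, obs[:, k], "o", color=color, label=label)
            ax.plot(grid, pred[:, k], "-", color=color)
        ax.set_xlabel("molar equivalents of ligand")
        ax.set_ylabel("species fraction")
        ax.legend()
        return ax


def lane_fractions(lane: LaneDensities, response=None) -> tuple[float, float, float]:
    """Species fractions (f0, f1, f2) from one lane's band densities.

    ``response`` optionally corrects per-band detection response
    (density is divided by it before normalisation).
    """
    d = np.array([lane.density_free, lane.density_b1, lane.density_b2], dtype=float)
    if response is not None:
        d = d / np.asarray(response, dtype=float)
    total = d.sum()
    if total <= 0:
        raise ValueError("lane has zero total density")
    f = d / total
    return (float(f[0]), float(f[1]), float(f[2]))


class EmsaModel:
    """Two-equivalent-site binding model over a series of gel lanes."""

    KD_BOUNDS = (1e-12, 1e-3)

    def __init__(self, lanes: list[LaneDensities], response=None):
        if len(lanes) < 3:
            raise ValueError("need at least 3 lanes")
        eq = np.array([l.equivalents for l in lanes])
        if eq.max() < 0.5:
            raise ValueError("titration does not constrain kd: all equivalents below 0.5")
        if eq.min() > 0:
            raise ValueError("titration must include a zero-equivalents lane")
        self.lanes = sorted(lanes, key=lambda l: l.equivalents)
        self.response = response
        self._obs = np.array([lane_fractions(l, response) for l in self.lanes])
        self._eq = np.array([l.equivalents for l in self.lanes])
        self._n0 = np.array([l.receptor_total for l in self.lanes])

    @classmethod
    def from_dataframe(cls, df, receptor_total: float, response=None) -> "EmsaModel":
        """Build from a table with columns lane_id, equivalents, density_free, density_b1, density_b2."""
        lanes = [
            LaneDensities(
                equivalents=float(r.equivalents),
                density_free=float(r.density_free),
                density_b1=float(r.density_b1),
                density_b2=float(r.density_b2),
                receptor_total=receptor_total,
                lane_id=str(getattr(r, "lane_id", "")),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(lanes, response=response)

    def predict(self, kd: float) -> np.ndarray:
        return np.array(
            [
                solve_two_site(n0, e * n0, kd).species_fractions
                for e, n0 in zip(self._eq, self._n0)
            ]
        )

    def rss(self, kd: float) -> float:
        resid = self._obs - self.predict(kd)
        return float(np.sum(resid * resid))

    def fit(self, n_grid: int = 61) -> EmsaFitResult:
        lo, hi = self.KD_BOUNDS
        grid = np.logspace(math.log10(lo), math.log10(hi), n_grid)
        rss = np.array([self.rss(k) for k in grid])
        i = int(np.argmin(rss))
        res = optimize.minimize_scalar(
            lambda lg: self.rss(10.0**lg),
            bounds=(math.log10(grid[max(i - 1, 0)]), math.log10(grid[min(i + 1, n_grid - 1)])),
            method="bounded",
            options={"xatol": 1e-12},
        )
        # zero-residual polish
        sol = optimize.least_squares(
            lambda lg: (self._obs - self.predict(10.0 ** lg[0])).ravel(),
            [res.x], method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        kd = 10.0 ** sol.x[0]
        rss_min = self.rss(kd)
        ci = self._profile_ci(kd, rss_min)
        return EmsaFitResult(
            kd_micro=kd,
            ci95=ci,
            per_lane_predicted=[tuple(row) for row in self.predict(kd)],
            rss=rss_min,
            _model=self,
        )

    def _profile_ci(self, kd: float, rss_min: float) -> tuple[float, float]:
        n = self._obs.size
        dof = n - 1
        if rss_min == 0.0:
            return (kd, kd)
        thr = rss_min * (1.0 + stats.f.ppf(0.95, 1, dof) / dof)

        def g(lg):
            return self.rss(10.0**lg) - thr

        lg_kd = math.log10(kd)
        lo_b, hi_b = math.log10(self.KD_BOUNDS[0]), math.log10(self.KD_BOUNDS[1])
        step = 0.25
        lower, upper = self.KD_BOUNDS[0], math.inf
        lg = lg_kd
        while lg - step >= lo_b and g(lg - step) < 0:
            lg -= step
        if lg - step >= lo_b:
            lower = 10.0 ** optimize.brentq(g, lg - step, lg_kd)
        lg = lg_kd
        while lg + step <= hi_b and g(lg + step) < 0:
            lg += step
        if lg + step <= hi_b:
            upper = 10.0 ** optimize.brentq(g, lg_kd, lg + step)
        return (lower, upper)


def fit_emsa(lanes: list[LaneDensities], response=None) -> EmsaFitResult:
    """Fit the microscopic K_D of the 2:1 model to a lane series."""
    return EmsaModel(lanes, response=response).fit()
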