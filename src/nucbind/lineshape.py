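"""Two-state chemical-exchange NMR line shapes and titration fitting.

The observed spin is a methyl group on the histone H3 tail that hops
between a free and a reader-bound environment.  Transverse magnetization
evolves under the 2x2 exchange (Bloch–McConnell) matrix

    L = [[ i*W_f - R2_f - k_fb ,            k_bf ],
         [            k_fb     , i*W_b - R2_b - k_bf ]]

whose kinetic part conserves population by construction.  The FID is
``1^T expm(L t) M0`` with ``M0`` the equilibrium populations; the
spectrum is its (apodized, zero-filled) Fourier transform.  Propagation
uses the exact eigendecomposition of the small constant matrix, so there
is no step-size error.

Populations along a titration are tied to the two-equivalent-site mass
balance of the nucleosome (two identical H3 tails per particle,
:func:`nucbind.equilibria.solve_two_site`): each tail site is free or
bound, and the free-ligand concentration at every titration point sets
the pseudo-first-order on-rate ``k_fb = koff * x / kd``.

Fitting estimates (K_D, koff, delta_omega, R2_free, R2_bound, free-state
offset) jointly across all traces of a titration, with one analytic
amplitude per trace; 95% intervals come from a likelihood-ratio grid
over (K_D, koff) or, alternatively, from posterior sampling (emcee).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .equilibria import EquilibriumParams, solve_two_site

__all__ = [
    "ExchangeState",
    "AcquisitionParams",
    "SpectrumTrace",
    "ExchangeFitResult",
    "pseudo_first_order_rates",
    "assemble_evolution_matrix",
    "simulate_fid",
    "spectrum_from_fid",
    "titration_lineshapes",
    "peak_positions",
    "ExchangeLineshapeModel",
    "fit_exchange",
]

#: observe-frequency scale relative to 1H; the 13C entry encodes the
#: documented 226.19 MHz carrier at a 900 MHz 1H field
GAMMA_RATIO = {"1H": 1.0, "13C": 226.19 / 900.0}


@dataclass(frozen=True)
class ExchangeState:
    """One chemical environment of the observed spin."""

    offset_ppm: float
    r2: float  # transverse relaxation rate, 1/s
    population: float = 1.0

    def __post_init__(self) -> None:
        if self.r2 <= 0:
            raise ValueError("r2 must be > 0")
        if not (0.0 <= self.population <= 1.0):
            raise ValueError("population must be in [0, 1]")


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition/processing settings for a simulated 1D trace."""

    h1_frequency_mhz: float = 900.0
    nucleus: str = "13C"
    sweep_width_ppm: float = 6.0
    n_points: int = 1024
    center_ppm: float = 0.0
    line_broadening_hz: float = 0.0

    def __post_init__(self) -> None:
        if self.nucleus not in GAMMA_RATIO:
            raise ValueError(f"nucleus must be one of {sorted(GAMMA_RATIO)}")
        n = self.n_points
        if n < 256 or (n & (n - 1)) != 0:
            raise ValueError("n_points must be a power of two >= 256")
        if self.sweep_width_ppm <= 0:
            raise ValueError("sweep_width_ppm must be > 0")

    @property
    def observe_frequency_mhz(self) -> float:
        return self.h1_frequency_mhz * GAMMA_RATIO[self.nucleus]

    @property
    def sweep_width_hz(self) -> float:
        return self.sweep_width_ppm * self.observe_frequency_mhz

    @property
    def dwell(self) -> float:
        return 1.0 / self.sweep_width_hz

    def validate_states(self, states) -> None:
        """Sweep must cover both offsets plus five maximal linewidths."""
        margin = 5.0 * max(s.r2 for s in states) / math.pi / self.observe_frequency_mhz
        lo = self.center_ppm - self.sweep_width_ppm / 2 + margin
        hi = self.center_ppm + self.sweep_width_ppm / 2 - margin
        for s in states:
            if not (lo <= s.offset_ppm <= hi):
                raise ValueError(
                    f"state offset {s.offset_ppm} ppm outside covered window [{lo:.3g}, {hi:.3g}]"
                )


@dataclass
class SpectrumTrace:
    """A 1D spectrum: ppm axis (ascending) and real intensities."""

    ppm: np.ndarray
    intensity: np.ndarray
    acquisition: AcquisitionParams | None = None
    ratio: float | None = None  # ligand:receptor molar ratio, if part of a titration

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape:
            raise ValueError("ppm and intensity must have the same length")


@dataclass
class ExchangeFitResult:
    """Joint line-shape fit of a titration series."""

    kd: float  # mol/L
    koff: float  # 1/s
    delta_omega: float  # ppm (bound - free)
    r2_free: float
    r2_bound: float
    offset_free: float  # ppm
    interval95_kd: tuple[float, float]
    interval95_koff: tuple[float, float]
    chi2: float
    flags: dict = field(default_factory=dict)
    _model: "ExchangeLineshapeModel | None" = field(repr=False, default=None, compare=False)

    def summary(self) -> str:
        def fmt_iv(iv, unit, scale=1.0):
            lo, hi = iv
            lo_s = f"{lo * scale:.3g}" if np.isfinite(lo) else "open"
            hi_s = f"{hi * scale:.3g}" if np.isfinite(hi) else "open"
            return f"[{lo_s}, {hi_s}] {unit}"

        lines = [
            "Two-state exchange line-shape fit (1:2 receptor:ligand mass balance)",
            "=" * 68,
            f"K_D          : {self.kd * 1e6:.3g} uM   95%: {fmt_iv(self.interval95_kd, 'uM', 1e6)}",
            f"k_off        : {self.koff:.3g} 1/s  95%: {fmt_iv(self.interval95_koff, '1/s')}",
            f"lifetime     : {1e3 / self.koff:.3g} ms",
            f"delta_omega  : {self.delta_omega:.4g} ppm",
            f"R2 free/bound: {self.r2_free:.3g} / {self.r2_bound:.3g} 1/s",
            f"chi2         : {self.chi2:.6g}",
        ]
        if self.flags:
            lines.append(f"flags        : {self.flags}")
        return "\n".join(lines)

    def best_fit_traces(self) -> list[SpectrumTrace]:
        if self._model is None:
            raise ValueError("result carries no model to simulate from")
        params = np.array(
            [math.log10(self.kd), math.log10(self.koff), self.delta_omega,
             self.r2_free, self.r2_bound, self.offset_free]
        )
        sims, scales = self._model._simulate_all(params)
        out = []
        for (sim, sc, ratio) in zip(sims, scales, self._model.ratios):
            out.append(SpectrumTrace(self._model.traces[0].ppm, sc * sim,
                                     self._model.acquisition, ratio))
        return out

    def plot(self, ax=None):
        """Overlay observed (points) and fitted (lines) traces."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fits = self.best_fit_traces()
        for obs, fit in zip(self._model.traces, fits):
            ax.plot(obs.ppm, obs.intensity, ".", ms=2)
            ax.plot(fit.ppm, fit.intensity, "-", label=f"ratio {fit.ratio:g}")
        ax.invert_xaxis()
        ax.set_xlabel(f"{self._model.acquisition.nucleus} (ppm)")
        ax.set_ylabel("intensity")
        ax.legend(fontsize="small")
        return ax


def pseudo_first_order_rates(kd: float, koff: float, free_ligand: float) -> tuple[float, float]:
    """Site exchange rates at a given free-ligand concentration.

    Returns ``(k_free_to_bound, k_bound_to_free)`` with
    ``k_free_to_bound = koff * x / kd`` so that the implied equilibrium
    bound population ``x / (kd + x)`` matches the per-site occupancy of
    the two-site mass balance.
    """
    if kd <= 0 or koff <= 0:
        raise ValueError("kd and koff must be > 0")
    if free_ligand < 0:
        raise ValueError("free_ligand must be >= 0")
    return koff * free_ligand / kd, koff


def assemble_evolution_matrix(states, rates, acquisition: AcquisitionParams) -> np.ndarray:
    """Complex 2x2 evolution matrix for two-site exchange.

    ``states`` is the (free, bound) pair; ``rates`` the
    (k_free_to_bound, k_bound_to_free) pair.  Offsets are taken relative
    to the acquisition carrier (``center_ppm``); the kinetic part has
    zero column sums.
    """
    (sf, sb), (k_fb, k_bf) = states, rates
    f_mhz = acquisition.observe_frequency_mhz
    w_f = 2.0 * math.pi * (sf.offset_ppm - acquisition.center_ppm) * f_mhz
    w_b = 2.0 * math.pi * (sb.offset_ppm - acquisition.center_ppm) * f_mhz
    return np.array(
        [
            [1j * w_f - sf.r2 - k_fb, k_bf],
            [k_fb, 1j * w_b - sb.r2 - k_bf],
        ],
        dtype=complex,
    )


def simulate_fid(evolution: np.ndarray, initial_magnetization, dwell: float, n_points: int) -> np.ndarray:
    """Observed FID ``1^T expm(L t_n) M0`` on a uniform time grid.

    Exact propagation by eigendecomposition; total magnetization at t=0
    equals ``sum(M0)``.
    """
    if dwell <= 0:
        raise ValueError("dwell must be > 0")
    m0 = np.asarray(initial_magnetization, dtype=complex)
    w, v = np.linalg.eig(evolution)
    if np.any(w.real > 1e-9):
        raise ValueError("divergent evolution (positive real eigenvalue); check R2/rates")
    c = np.linalg.solve(v, m0)
    weights = v.sum(axis=0) * c  # 1^T V diag(c)
    t = dwell * np.arange(n_points)
    return np.exp(np.outer(t, w)) @ weights


def spectrum_from_fid(fid: np.ndarray, acquisition: AcquisitionParams) -> SpectrumTrace:
    """Apodize, zero-fill (x2) and Fourier-transform an FID to a trace.

    The first FID point is halved (trapezoidal correction to the discrete
    transform) and the spectrum scaled so that the integral over the ppm
    axis in Hz equals the total t=0 magnetization.
    """
    n = fid.size
    t = acquisition.dwell * np.arange(n)
    apod = np.exp(-math.pi * acquisition.line_broadening_hz * t)
    x = fid * apod
    x[0] *= 0.5
    nfft = 2 * n
    spec = 2.0 * acquisition.dwell * np.fft.fftshift(np.fft.fft(x, nfft)).real
    freq_hz = np.fft.fftshift(np.fft.fftfreq(nfft, acquisition.dwell))
    ppm = acquisition.center_ppm + freq_hz / acquisition.observe_frequency_mhz
    return SpectrumTrace(ppm, spec, acquisition)


def titration_lineshapes(
    eq: EquilibriumParams,
    koff: float,
    states,
    acquisition: AcquisitionParams,
    receptor_total: float,
    ratios,
) -> list[SpectrumTrace]:
    """Simulate one trace per ligand:receptor molar ratio.

    At each ratio the 1:2 (receptor:ligand) mass balance gives the free
    ligand and per-site occupancy; the occupancy sets the equilibrium
    populations of the (free, bound) states and the free ligand the
    pseudo-first-order on-rate.  Ratio 0 reproduces the free spectrum.
    """
    ratios = list(ratios)
    if 0 not in ratios and 0.0 not in ratios:
        raise ValueError("ratios must include 0 (free-state reference)")
    acquisition.validate_states(states)
    sf, sb = states
    out = []
    for ratio in ratios:
        mix = solve_two_site(receptor_total, ratio * receptor_total, eq.kd_micro)
        theta = mix.site_occupancy
        rates = pseudo_first_order_rates(eq.kd_micro, koff, mix.free_ligand)
        ev = assemble_evolution_matrix(
            (replace(sf, population=1 - theta), replace(sb, population=theta)),
            rates,
            acquisition,
        )
        fid = simulate_fid(ev, (1 - theta, theta), acquisition.dwell, acquisition.n_points)
        trace = spectrum_from_fid(fid, acquisition)
        trace.ratio = float(ratio)
        out.append(trace)
    return out


def peak_positions(traces) -> list[tuple[float, float]]:
    """(ratio, ppm) of each trace's global maximum, parabolic-refined."""
    out = []
    for tr in traces:
        y = tr.intensity
        if np.ptp(y) == 0:
            raise ValueError("flat trace has no peak")
        i = int(np.argmax(y))
        ppm = tr.ppm[i]
        if 0 < i < y.size - 1:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            if denom != 0:
                delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
                ppm = ppm + delta * (tr.ppm[1] - tr.ppm[0])
        out.append((tr.ratio if tr.ratio is not None else math.nan, float(ppm)))
    return out


class ExchangeLineshapeModel:
    """Joint fit of a line-shape titration under the 1:2 mass balance.

    Parameters
    ----------
    traces : list of SpectrumTrace
        Observed 1D traces, all on the same ppm axis, including the
        free reference (ratio 0).
    ratios : sequence of float
        Ligand:receptor molar ratio of each trace.
    receptor_total : float
        Receptor (nucleosome) concentration, mol/L.
    acquisition : AcquisitionParams
        Settings used to simulate model traces.
    """

    def __init__(self, traces, ratios, receptor_total, acquisition: AcquisitionParams):
        if len(traces) != len(ratios):
            raise ValueError("one ratio per trace required")
        if len(traces) < 4:
            raise ValueError("need >= 4 traces including the free reference")
        if 0.0 not in [float(r) for r in ratios]:
            raise ValueError("titration must include the free reference (ratio 0)")
        axis = traces[0].ppm
        for tr in traces[1:]:
            if not np.allclose(tr.ppm, axis):
                raise ValueError("all traces must share one ppm axis")
        self.traces = list(traces)
        self.ratios = [float(r) for r in ratios]
        self.receptor_total = float(receptor_total)
        self.acquisition = acquisition
        self._obs = np.stack([tr.intensity for tr in traces])

    # -- simulation ----------------------------------------------------------
    def _simulate_all(self, params: np.ndarray):
        """Simulated traces and analytic per-trace scales for one parameter set.

        ``params`` = (log10 kd, log10 koff, delta_omega ppm, r2_free,
        r2_bound, offset_free ppm).
        """
        kd, koff = 10.0 ** params[0], 10.0 ** params[1]
        dw, r2f, r2b, off = params[2], params[3], params[4], params[5]
        states = (ExchangeState(off, r2f), ExchangeState(off + dw, r2b))
        sims = titration_lineshapes(
            EquilibriumParams(kd, 2), koff, states, self.acquisition, self.receptor_total, self.ratios
        )
        sim = np.stack([s.intensity for s in sims])
        denom = np.sum(sim * sim, axis=1)
        scales = np.where(denom > 0, np.sum(self._obs * sim, axis=1) / np.where(denom > 0, denom, 1.0), 0.0)
        return sim, scales

    def _residuals(self, params: np.ndarray) -> np.ndarray:
        sim, scales = self._simulate_all(params)
        return (self._obs - scales[:, None] * sim).ravel()

    def chi2(self, params: np.ndarray) -> float:
        r = self._residuals(params)
        return float(r @ r)

    # -- fitting ---------------------------------------------------------------
    def _initial_guesses(self, bounds):
        pos = peak_positions(self.traces)
        off0 = pos[self.ratios.index(0.0)][1]
        last = max(range(len(self.ratios)), key=lambda i: self.ratios[i])
        theta_guess = min(0.95, self.ratios[last] / 2.0)
        dw0 = (pos[last][1] - off0) / max(theta_guess, 0.1)
        if abs(dw0) < 1e-3:
            dw0 = 0.1
        # free-state linewidth -> R2 estimate
        free = self.traces[self.ratios.index(0.0)]
        half = free.intensity.max() / 2
        above = np.nonzero(free.intensity > half)[0]
        fwhm_hz = (free.ppm[above[-1]] - free.ppm[above[0]]) * self.acquisition.observe_frequency_mhz
        r2f0 = max(math.pi * fwhm_hz - math.pi * self.acquisition.line_broadening_hz, 1.0)
        n0 = self.receptor_total
        starts = []
        for kd0 in (n0 / 100, n0 / 10, n0):
            for koff0 in (100.0, 500.0, 2000.0):
                starts.append(
                    np.array([math.log10(kd0), math.log10(koff0), dw0, r2f0, 5 * r2f0, off0])
                )
        lo = np.array([math.log10(bounds["kd"][0]), math.log10(bounds["koff"][0]),
                       bounds["delta_omega"][0], bounds["r2"][0], bounds["r2"][0],
                       off0 - 0.5])
        hi = np.array([math.log10(bounds["kd"][1]), math.log10(bounds["koff"][1]),
                       bounds["delta_omega"][1], bounds["r2"][1], bounds["r2"][1],
                       off0 + 0.5])
        starts = [np.clip(s, lo + 1e-9, hi - 1e-9) for s in starts]
        return starts, (lo, hi)

    def fit(self, bounds: dict | None = None, compute_ci: bool = True,
            ci_method: str = "profile", n_starts: int = 2) -> ExchangeFitResult:
        """Least-squares fit with multi-start, then optional 95% intervals.

        ``bounds`` maps 'kd' (mol/L), 'koff' (1/s), 'delta_omega' (ppm) and
        'r2' (1/s) to (low, high) pairs.
        """
        default_bounds = {
            "kd": (1e-9, 1e-2),
            "koff": (1.0, 1e5),
            "delta_omega": (-2.0, 2.0),
            "r2": (0.5, 500.0),
        }
        if bounds:
            default_bounds.update(bounds)
        bounds = default_bounds
        starts, (lo, hi) = self._initial_guesses(bounds)
        # rank the start grid by a single cheap chi2 evaluation
        starts.sort(key=self.chi2)
        best = None
        for s in starts[:n_starts]:
            sol = optimize.least_squares(
                self._residuals, s, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        params = best.x
        chi2 = self.chi2(params)
        flags: dict = {}
        if compute_ci:
            iv_kd, iv_koff = self._intervals(params, chi2, flags, method=ci_method)
        else:
            iv_kd = (math.nan, math.nan)
            iv_koff = (math.nan, math.nan)
        return ExchangeFitResult(
            kd=10.0 ** params[0],
            koff=10.0 ** params[1],
            delta_omega=params[2],
            r2_free=params[3],
            r2_bound=params[4],
            offset_free=params[5],
            interval95_kd=iv_kd,
            interval95_koff=iv_koff,
            chi2=chi2,
            flags=flags,
            _model=self,
        )

    # -- intervals -------------------------------------------------------------
    def _intervals(self, params, chi2_min, flags, method="profile",
                   half_decades=2.0, step=0.1):
        """95% likelihood-ratio intervals for (kd, koff).

        For each parameter the chi2 profile (minimised over the other rate
        parameter on its log axis; shape parameters fixed at the best fit,
        per-trace scales analytic) is walked outward in ``step``-decade
        increments until it crosses the F(1, dof) threshold, then the
        crossing is refined by bisection.  A profile that never crosses
        before ``half_decades`` from the optimum is reported open on that
        side (one-sided interval) with a flag.
        """
        if method == "mcmc":
            return self._intervals_mcmc(params, flags)
        n = self._obs.size
        p_fit = 6 + len(self.traces)
        dof = max(n - p_fit, 1)
        if chi2_min <= 1e-16 * float(np.sum(self._obs * self._obs)):
            # residuals at machine precision: the interval collapses
            return (10.0 ** params[0],) * 2, (10.0 ** params[1],) * 2
        thr = chi2_min * (1.0 + stats.f.ppf(0.95, 1, dof) / dof)

        def profile(axis: int, lg_value: float) -> float:
            other = 1 - axis
            p = params.copy()
            p[axis] = lg_value

            def inner(lg_other):
                p[other] = lg_other
                return self.chi2(p)

            res = optimize.minimize_scalar(
                inner,
                bounds=(params[other] - half_decades, params[other] + half_decades),
                method="bounded",
                options={"xatol": 1e-4},
            )
            return res.fun

        def one_side(axis: int, direction: int, name: str) -> float:
            lg0 = params[axis]
            lg = lg0
            while abs(lg - lg0) < half_decades:
                nxt = lg + direction * step
                if profile(axis, nxt) > thr:
                    if profile(axis, lg) - thr >= 0:
                        return lg  # crossing already at the inner bracket edge
                    return optimize.brentq(
                        lambda x: profile(axis, x) - thr, min(lg, nxt), max(lg, nxt),
                        xtol=1e-4,
                    )
                lg = nxt
            side = "lower" if direction < 0 else "upper"
            flags[f"{name}_{side}"] = "open (chi2 surface flat in this direction)"
            return -math.inf if direction < 0 else math.inf

        intervals = []
        for axis, name in ((0, "kd"), (1, "koff")):
            lo = one_side(axis, -1, name)
            hi = one_side(axis, +1, name)
            if not np.isfinite(lo) and not np.isfinite(hi):
                flags[name] = "unidentifiable: chi2 surface flat in both directions"
            intervals.append(
                (10.0 ** lo if np.isfinite(lo) else 0.0,
                 10.0 ** hi if np.isfinite(hi) else math.inf)
            )
        return intervals[0], intervals[1]

    def _intervals_mcmc(self, params, flags, n_walkers=16, n_steps=400, seed=0):
        """Posterior-sampling intervals (flat priors in the log parameters)."""
        import emcee

        n = self._obs.size
        chi2_min = self.chi2(params)
        sigma2 = chi2_min / max(n - 6 - len(self.traces), 1)

        def log_prob(theta):
            p = params.copy()
            p[0], p[1] = theta
            if not (-9 <= theta[0] <= -2 and 0 <= theta[1] <= 5):
                return -math.inf
            return -0.5 * self.chi2(p) / sigma2

        rng = np.random.default_rng(seed)
        p0 = params[:2] + 0.01 * rng.standard_normal((n_walkers, 2))
        sampler = emcee.EnsembleSampler(n_walkers, 2, log_prob)
        sampler.run_mcmc(p0, n_steps, progress=False)
        chain = sampler.get_chain(discard=n_steps // 2, flat=True)
        lo_kd, hi_kd = np.percentile(chain[:, 0], [2.5, 97.5])
        lo_ko, hi_ko = np.percentile(chain[:, 1], [2.5, 97.5])
        return (10.0 ** lo_kd, 10.0 ** hi_kd), (10.0 ** lo_ko, 10.0 ** hi_ko)


def fit_exchange(traces, ratios, receptor_total, acquisition: AcquisitionParams,
                 bounds: dict | None = None, **kwargs) -> ExchangeFitResult:
    """Jointly fit (K_D, koff, delta_omega, R2s) to a titration of 1D traces."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return ExchangeLineshapeModel(traces, ratios, receptor_total, acquisition).fit(
            bounds=bounds, **kwargs
        )
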