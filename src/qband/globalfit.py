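"""Global kinetic analysis of transient-absorption maps.

A multi-exponential compartment model with a Gaussian IRF (and optional
probe chirp) is fitted to the full delta-A(delay, wavenumber) matrix by
variable projection: only the nonlinear parameters (lifetimes in log space,
optionally time zero and IRF width) are iterated, while the per-component
spectra are solved by linear projection at every step.  A sequential
topology yields evolution-associated spectra (EAS), a parallel topology
decay-associated spectra (DAS); the two are linked by the exact linear
Bateman transform, so both are reported from a single fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .kinetics import (
    InstrumentModel,
    KineticScheme,
    SpeciesSpectra,
    exponential_basis,
    sequential_amplitudes,
)
from .tamap import TAMap

__all__ = [
    "GlobalKineticModel",
    "GlobalFitResult",
    "ModelSelection",
    "fit_global",
    "select_order",
    "eas_to_das",
    "das_to_eas",
]


def eas_to_das(eas: SpeciesSpectra, scheme: KineticScheme) -> SpeciesSpectra:
    """Exact linear transform from sequential-model EAS to parallel DAS."""
    A = sequential_amplitudes(scheme.lifetimes)
    return SpeciesSpectra(axis=eas.axis, spectra=A.T @ eas.spectra, kind="DAS")


def das_to_eas(das: SpeciesSpectra, scheme: KineticScheme) -> SpeciesSpectra:
    """Inverse of `eas_to_das` (singular for repeated lifetimes)."""
    A = sequential_amplitudes(scheme.lifetimes)
    return SpeciesSpectra(
        axis=das.axis, spectra=np.linalg.solve(A.T, das.spectra), kind="EAS"
    )


@dataclass
class GlobalFitResult:
    """Estimates, uncertainties and diagnostics of one global fit."""

    scheme: KineticScheme
    eas: SpeciesSpectra | None
    das: SpeciesSpectra
    instrument: InstrumentModel
    residual_matrix: np.ndarray
    covariance: np.ndarray  # of the free nonlinear parameters
    lifetime_stderr: np.ndarray
    ssr: float
    n_points: int
    n_parameters: int
    success: bool
    message: str = ""
    conditioning_warning: bool = False

    @property
    def lifetimes(self) -> np.ndarray:
        return self.scheme.lifetimes

    @property
    def bic(self) -> float:
        n, p = self.n_points, self.n_parameters
        return n * np.log(self.ssr / n) + p * np.log(n)

    def reconstruction(self) -> np.ndarray:
        """Model matrix; data = reconstruction + residual_matrix exactly."""
        return self._data - self.residual_matrix

    _data: np.ndarray = field(default=None, repr=False)

    def summary(self) -> str:
        rows = []
        for i, (tau, fx, se) in enumerate(
            zip(self.scheme.lifetimes, self.scheme.fixed_mask, self.lifetime_stderr)
        ):
            rows.append(
                {
                    "component": i + 1,
                    "lifetime_fs": tau,
                    "stderr_fs": np.nan if fx else se,
                    "fixed": bool(fx),
                }
            )
        tbl = pd.DataFrame(rows)
        head = (
            f"Global kinetic fit ({self.scheme.topology}, "
            f"{self.scheme.n_components} components)\n"
            f"  n_points={self.n_points}  SSR={self.ssr:.6g}  BIC={self.bic:.2f}\n"
            f"  IRF FWHM={self.instrument.irf_fwhm:.3g} fs  t0={self.instrument.t0:.3g} fs\n"
        )
        return head + tbl.to_string(index=False, float_format=lambda v: f"{v:.6g}")

    def plot(self, ax=None):  # pragma: no cover - convenience only
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        spectra = self.eas if self.eas is not None else self.das
        for i, (tau, s) in enumerate(zip(self.lifetimes, spectra.spectra)):
            ax.plot(spectra.axis, s, label=f"{tau:.3g} fs")
        ax.set_xlabel("wavenumber / cm$^{-1}$")
        ax.set_ylabel(r"$\Delta A$ / mOD")
        ax.legend()
        return ax


class GlobalKineticModel:
    """Variable-projection global fit of one TA map.

    Parameters
    ----------
    data : TAMap
    topology : {"sequential", "parallel"}
    n_components : int
    instrument : InstrumentModel
        Initial (or fixed) IRF width, time zero and chirp.
    fixed_mask : bool array, optional
        Per-lifetime "hold fixed" flags.
    fit_t0, fit_irf : bool
        Also optimize the global time zero / the IRF width.
    """

    #: bounds for log(lifetime / fs)
    _LOG_TAU_BOUNDS = (np.log(0.1), np.log(1e10))

    def __init__(
        self,
        data: TAMap,
        topology: str = "sequential",
        n_components: int = 1,
        instrument: InstrumentModel | None = None,
        fixed_mask=None,
        fit_t0: bool = False,
        fit_irf: bool = False,
    ):
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        self.data = data
        self.topology = topology
        self.n_components = n_components
        self.instrument = instrument or InstrumentModel()
        self.fixed_mask = (
            np.zeros(n_components, dtype=bool)
            if fixed_mask is None
            else np.asarray(fixed_mask, dtype=bool)
        )
        if self.fixed_mask.size != n_components:
            raise ValueError("fixed_mask length must equal n_components")
        self.fit_t0 = fit_t0
        self.fit_irf = fit_irf
        self._cond_warn = False

    # -- variable projection core -------------------------------------------------

    def _unpack(self, p, fixed_taus, init_taus):
        taus = np.array(init_taus, dtype=float)
        free = ~self.fixed_mask
        taus[free] = np.exp(p[: free.sum()])
        taus[self.fixed_mask] = fixed_taus[self.fixed_mask]
        i = free.sum()
        t0 = p[i] if self.fit_t0 else self.instrument.t0
        i += self.fit_t0
        irf = np.exp(p[i]) if self.fit_irf else self.instrument.irf_fwhm
        return taus, t0, irf

    def _project(self, taus, t0, irf):
        """Solve the conditionally linear spectra; return (coef, residual)."""
        d = self.data
        t0_axis = InstrumentModel(
            irf_fwhm=irf,
            t0=t0,
            chirp_coeffs=self.instrument.chirp_coeffs,
            chirp_center=self.instrument.chirp_center,
        ).t0_of(d.axis)
        C = exponential_basis(d.delays[:, None], taus, irf, t0_axis)  # (t, w, k)
        G = np.einsum("twk,twl->wkl", C, C)
        b = np.einsum("twk,tw->wk", C, d.dA)
        cond = np.linalg.cond(G)
        if np.max(cond) > 1e10:
            self._cond_warn = True
        try:
            coef = np.linalg.solve(G, b[..., None])[..., 0]  # (w, k) DAS per lambda
        except np.linalg.LinAlgError:
            self._cond_warn = True
            coef = np.stack(
                [np.linalg.lstsq(G[w], b[w], rcond=None)[0] for w in range(G.shape[0])]
            )
        model = np.einsum("twk,wk->tw", C, coef)
        return C, coef, d.dA - model

    def _residual_vec(self, p, fixed_taus, init_taus):
        taus, t0, irf = self._unpack(p, fixed_taus, init_taus)
        return self._project(taus, t0, irf)[2].ravel()

    # -- public API ---------------------------------------------------------------

    def fit(self, init_lifetimes, max_nfev: int = 400) -> GlobalFitResult:
        """Run the fit from the given initial lifetimes (fs)."""
        init_taus = np.atleast_1d(np.asarray(init_lifetimes, dtype=float))
        if init_taus.size != self.n_components:
            raise ValueError("init_lifetimes length must equal n_components")
        if np.any(init_taus <= 0):
            raise ValueError("lifetimes must be > 0")
        span = self.data.delays[-1] - self.data.delays[0]
        free_taus = init_taus[~self.fixed_mask]
        if free_taus.size and span < 3 * free_taus.min():
            warnings.warn("delay span is short relative to the smallest free lifetime")
        self._cond_warn = False

        free = ~self.fixed_mask
        p0 = list(np.log(init_taus[free]))
        lo = [self._LOG_TAU_BOUNDS[0]] * free.sum()
        hi = [self._LOG_TAU_BOUNDS[1]] * free.sum()
        if self.fit_t0:
            p0.append(self.instrument.t0)
            lo.append(self.instrument.t0 - span)
            hi.append(self.instrument.t0 + span)
        if self.fit_irf:
            p0.append(np.log(self.instrument.irf_fwhm))
            lo.append(np.log(1e-3))
            hi.append(np.log(span))

        sol = least_squares(
            self._residual_vec,
            np.asarray(p0),
            bounds=(lo, hi),
            args=(init_taus, init_taus),
            method="trf",
            x_scale="jac",
            max_nfev=max_nfev,
        )
        if not sol.success:
            raise RuntimeError(f"global fit did not converge: {sol.message}")

        taus, t0, irf = self._unpack(sol.x, init_taus, init_taus)
        scheme = KineticScheme(
            lifetimes=taus, topology=self.topology, fixed_mask=self.fixed_mask
        )
        _, coef, resid = self._project(taus, t0, irf)
        das = SpeciesSpectra(axis=self.data.axis, spectra=coef.T, kind="DAS")
        eas = None
        if self.topology == "sequential":
            eas = das_to_eas(das, scheme)

        m, n = sol.fun.size, sol.x.size
        dof = max(m - n - self.n_components * self.data.axis.size, 1)
        s2 = 2.0 * sol.cost / dof
        JTJ = sol.jac.T @ sol.jac
        try:
            cov = s2 * np.linalg.inv(JTJ)
        except np.linalg.LinAlgError:
            cov = np.full((n, n), np.nan)
        stderr = np.zeros(self.n_components)
        stderr[free] = taus[free] * np.sqrt(np.clip(np.diag(cov)[: free.sum()], 0, None))

        inst = InstrumentModel(
            irf_fwhm=irf,
            t0=t0,
            chirp_coeffs=self.instrument.chirp_coeffs,
            chirp_center=self.instrument.chirp_center,
        )
        res = GlobalFitResult(
            scheme=scheme,
            eas=eas,
            das=das,
            instrument=inst,
            residual_matrix=resid,
            covariance=cov,
            lifetime_stderr=stderr,
            ssr=float(2.0 * sol.cost),
            n_points=m,
            n_parameters=n + self.n_components * self.data.axis.size,
            success=True,
            message=sol.message,
            conditioning_warning=self._cond_warn,
        )
        res._data = self.data.dA
        if self._cond_warn:
            warnings.warn("near-singular design (close lifetimes): spectra ill-determined")
        return res


def fit_global(
    ta_map: TAMap,
    topology: str,
    n_components: int,
    init_lifetimes,
    fixed_mask=None,
    instrument: InstrumentModel | None = None,
    fit_t0: bool = False,
    fit_irf: bool = False,
) -> GlobalFitResult:
    """Functional wrapper around `GlobalKineticModel.fit`."""
    model = GlobalKineticModel(
        ta_map,
        topology=topology,
        n_components=n_components,
        instrument=instrument,
        fixed_mask=fixed_mask,
        fit_t0=fit_t0,
        fit_irf=fit_irf,
    )
    return model.fit(init_lifetimes)


@dataclass
class ModelSelection:
    """Nested F-test model-order scan."""

    candidate_orders: list
    statistics: pd.DataFrame
    selected: int
    alpha: float


#: initial-lifetime ladder scales (lo_fs, hi_fraction_of_span) for multistart
_LADDERS = ((60.0, 1.0 / 16.0), (120.0, 1.0 / 8.0), (200.0, 1.0 / 4.0))


def _ladder_inits(order: int, delays: np.ndarray, fix_last: float | None, ladder):
    t_max = delays[-1]
    lo, hi_frac = ladder
    n_free = order - (fix_last is not None)
    if n_free <= 0:
        return np.array([fix_last])
    inits = np.geomspace(lo, max(t_max * hi_frac, 4 * lo), max(n_free, 1))
    if fix_last is not None:
        inits = np.append(inits, fix_last)
    return inits


def select_order(
    ta_map: TAMap,
    topology: str,
    orders,
    alpha: float = 0.05,
    instrument: InstrumentModel | None = None,
    fix_last: float | None = None,
    fit_t0: bool = False,
) -> ModelSelection:
    """Choose the number of kinetic components by incremental F-tests.

    Orders are fitted in ascending sequence; the selected order is the
    smallest one for which adding the next component no longer improves the
    residual sum of squares significantly at level ``alpha``.  BIC is
    reported alongside.  ``fix_last`` holds the longest lifetime of every
    candidate fixed (e.g. a fluorescence lifetime the delay window cannot
    constrain).
    """
    orders = list(orders)
    if any(b <= a for a, b in zip(orders, orders[1:])) or not orders:
        raise ValueError("orders must be non-empty and strictly increasing")
    fits = {}
    rows = []
    for order in orders:
        mask = np.zeros(order, dtype=bool)
        if fix_last is not None:
            mask[-1] = True
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # best-of-ladders multistart: nested F-tests need each order at
            # its global minimum, not a local basin
            for ladder in _LADDERS:
                inits = _ladder_inits(order, ta_map.delays, fix_last, ladder)
                cand = fit_global(
                    ta_map,
                    topology,
                    order,
                    inits,
                    fixed_mask=mask,
                    instrument=instrument,
                    fit_t0=fit_t0,
                )
                if res is None or cand.ssr < res.ssr:
                    res = cand
        fits[order] = res
        rows.append(
            {
                "order": order,
                "ssr": res.ssr,
                "n_parameters": res.n_parameters,
                "bic": res.bic,
                "residual_variance": res.ssr / res.n_points,
            }
        )
    stats_df = pd.DataFrame(rows)
    data_ss = float(np.sum(ta_map.dA**2))
    pvals = [np.nan]
    for (o1, r1), (o2, r2) in zip(list(fits.items())[:-1], list(fits.items())[1:]):
        dp = r2.n_parameters - r1.n_parameters
        dof2 = max(r2.n_points - r2.n_parameters, 1)
        if r1.ssr <= 1e-18 * data_ss:
            # the smaller model already fits to rounding: no room to improve
            pvals.append(1.0)
            continue
        F = ((r1.ssr - r2.ssr) / dp) / (r2.ssr / dof2)
        pvals.append(float(stats.f.sf(max(F, 0.0), dp, dof2)))
    stats_df["p_next_vs_this"] = pvals[1:] + [np.nan]
    selected = orders[-1]
    for i, order in enumerate(orders[:-1]):
        if stats_df["p_next_vs_this"].iloc[i] >= alpha:
            selected = order
            break
    return ModelSelection(
        candidate_orders=orders, statistics=stats_df, selected=selected, alpha=alpha
    )
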