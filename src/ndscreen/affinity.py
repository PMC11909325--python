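"""Steady-state 1:1 affinity fitting of titration series.

For a 1:1 interaction read at steady state, the equilibrium response at
analyte concentration C is

    R_eq(C) = Rmax * C / (K_D + C)

and (K_D, Rmax) are estimated by unweighted nonlinear least squares over a
titration series of corrected report points. The typical use here is
characterizing the control compound (a type-II azole inhibitor binding the
P450 heme iron 1:1) and checking the fitted K_D against its literature
window as an assay-health QC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import FitError, ValidationError

__all__ = ["SteadyStateAffinity", "AffinityResults", "QCResult", "control_qc"]


def _binding_isotherm(c: np.ndarray, rmax: float, kd: float) -> np.ndarray:
    return rmax * c / (kd + c)


@dataclass(frozen=True)
class QCResult:
    passed: bool
    message: str


@dataclass
class AffinityResults:
    """Estimates from a steady-state affinity fit.

    kd, rmax : point estimates (µM, RU); kd_se, rmax_se their standard
    errors from the fit covariance; residual_norm the Euclidean norm of the
    fit residuals.
    """

    kd: float
    rmax: float
    kd_se: float
    rmax_se: float
    residual_norm: float
    converged: bool
    nobs: int
    analyte_id: Optional[str] = None
    model: Optional["SteadyStateAffinity"] = None

    def predict(self, concentrations: Sequence[float]) -> np.ndarray:
        return _binding_isotherm(np.asarray(concentrations, dtype=float),
                                 self.rmax, self.kd)

    def control_qc(self, kd_lo: float = 10.0, kd_hi: float = 20.0) -> QCResult:
        return control_qc(self, (kd_lo, kd_hi))

    def summary(self) -> str:
        name = self.analyte_id or "analyte"
        lines = [
            "Steady-state 1:1 affinity fit",
            "=============================",
            f"analyte:        {name}",
            f"n observations: {self.nobs}",
            f"K_D  = {self.kd:10.4g} uM   (se {self.kd_se:.3g})",
            f"Rmax = {self.rmax:10.4g} RU   (se {self.rmax_se:.3g})",
            f"residual norm = {self.residual_norm:.4g} RU",
            f"converged: {self.converged}",
        ]
        return "\n".join(lines)


class SteadyStateAffinity:
    """Steady-state 1:1 binding model for a titration series.

    Parameters
    ----------
    concentrations : sequence of float
        Analyte concentrations, µM (>= 4 distinct values required).
    responses : sequence of float
        Corrected steady-state report points, RU, matched to
        ``concentrations``.
    analyte_id, channel_id : str, optional
        Labels carried through to the results.
    """

    def __init__(
        self,
        concentrations: Sequence[float],
        responses: Sequence[float],
        analyte_id: Optional[str] = None,
        channel_id: Optional[str] = None,
    ) -> None:
        c = np.asarray(concentrations, dtype=float)
        r = np.asarray(responses, dtype=float)
        if c.shape != r.shape or c.ndim != 1:
            raise ValidationError("concentrations and responses must be "
                                  "1-D and of equal length")
        if np.any(c < 0):
            raise ValidationError("concentrations must be >= 0")
        if np.unique(c).size < 4:
            raise ValidationError("titration needs >= 4 distinct "
                                  "concentrations")
        self.concentrations = c
        self.responses = r
        self.analyte_id = analyte_id
        self.channel_id = channel_id

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        concentration_col: str = "concentration_uM",
        response_col: str = "response_RU",
        **kwargs,
    ) -> "SteadyStateAffinity":
        return cls(table[concentration_col].to_numpy(),
                   table[response_col].to_numpy(), **kwargs)

    def _initial_guess(self) -> tuple[float, float]:
        rmax0 = 1.2 * float(self.responses.max())
        order = np.argsort(self.concentrations)
        c_sorted = self.concentrations[order]
        r_sorted = self.responses[order]
        half = rmax0 / 2.0
        # first concentration where the (monotone-ish) response crosses half
        kd0 = float(np.interp(half, r_sorted, c_sorted))
        if not kd0 > 0:
            kd0 = float(np.median(c_sorted[c_sorted > 0]) or 1.0)
        return rmax0, kd0

    def fit(self, max_restarts: int = 5) -> AffinityResults:
        """Nonlinear least squares on R_eq(C); bounded random restarts.

        Raises :class:`FitError` when all responses are zero or no restart
        converges. Warns when the sampled concentrations do not reach the
        fitted K_D (the estimate is then poorly constrained).
        """
        if np.allclose(self.responses, 0.0):
            raise FitError("all responses are zero; nothing to fit")
        rmax0, kd0 = self._initial_guess()
        rng = np.random.default_rng(12345)
        last_err: Optional[Exception] = None
        for attempt in range(max_restarts):
            p0 = (rmax0, kd0) if attempt == 0 else (
                rmax0 * float(rng.uniform(0.5, 2.0)),
                kd0 * float(rng.uniform(0.2, 5.0)),
            )
            try:
                popt, pcov = curve_fit(
                    _binding_isotherm, self.concentrations, self.responses,
                    p0=p0, bounds=([0.0, 0.0], [np.inf, np.inf]),
                    maxfev=10000,
                )
            except (RuntimeError, ValueError) as exc:
                last_err = exc
                continue
            rmax, kd = float(popt[0]), float(popt[1])
            if not (kd > 0 and rmax > 0):
                last_err = FitError(f"degenerate estimates kd={kd}, rmax={rmax}")
                continue
            se = np.sqrt(np.diag(pcov))
            resid = self.responses - _binding_isotherm(
                self.concentrations, rmax, kd)
            if kd > float(self.concentrations.max()):
                import warnings
                warnings.warn(
                    f"fitted K_D ({kd:.3g} uM) exceeds the highest sampled "
                    f"concentration ({self.concentrations.max():.3g} uM); "
                    "estimate is extrapolated", stacklevel=2)
            return AffinityResults(
                kd=kd, rmax=rmax,
                kd_se=float(se[1]), rmax_se=float(se[0]),
                residual_norm=float(np.linalg.norm(resid)),
                converged=True, nobs=int(self.concentrations.size),
                analyte_id=self.analyte_id, model=self,
            )
        raise FitError(
            f"steady-state fit failed after {max_restarts} restarts "
            f"(last error: {last_err}); initial guess rmax0={rmax0:.3g}, "
            f"kd0={kd0:.3g}"
        )


def control_qc(fit: AffinityResults,
               expected_range: tuple[float, float] = (10.0, 20.0)) -> QCResult:
    """Assay-health check: is the control K_D inside its expected window?

    Bounds are inclusive. The control compound's affinity is a proxy for the
    amount of active target left on the surface, so a drifting K_D (or
    vanishing Rmax) signals a degraded surface.
    """
    lo, hi = expected_range
    if not fit.converged:
        return QCResult(False, "fit did not converge")
    tol = 1e-9 * max(abs(lo), abs(hi), 1.0)  # inclusive up to float noise
    if lo - tol <= fit.kd <= hi + tol:
        return QCResult(
            True,
            f"control K_D = {fit.kd:.3g} uM within expected [{lo:g}, {hi:g}] uM",
        )
    return QCResult(
        False,
        f"control K_D = {fit.kd:.3g} uM outside expected [{lo:g}, {hi:g}] uM",
    )
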