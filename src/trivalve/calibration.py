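"""Material calibration with a model/results interface.

``MaterialCalibration`` wraps least-squares fitting of a constitutive model
to stress-strain curves the way statistical modelling packages pair a model
object with a results object: build the model from data, call ``fit()``, and
inspect the returned :class:`CalibrationResult` (parameter table, per-curve
RMSE, summary text, diagnostic plot).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constitutive import (AhyperParams, HyperfoamParams, StressStrainCurve,
                           FitResult, fit_model, mode_response)

__all__ = ["MaterialCalibration", "CalibrationResult"]


class MaterialCalibration:
    """Least-squares calibration of a hyperelastic model to test curves.

    Parameters
    ----------
    curves : stress-strain curves (true strain / true stress [MPa])
    model  : "ahyper" (anisotropic, tension) or "hyperfoam" (foam, compression)
    weights: optional per-curve weights
    """

    def __init__(self, curves: Sequence[StressStrainCurve],
                 model: str = "ahyper",
                 weights: Sequence[float] | None = None):
        if not curves:
            raise ValueError("at least one curve required")
        self.curves = list(curves)
        self.model = model
        self.weights = weights

    @classmethod
    def from_dataframe(cls, df, model: str = "ahyper", **kw) -> "MaterialCalibration":
        """Build from a table with columns mode, direction, true_strain,
        true_stress_MPa (the CSV curve dialect)."""
        curves = []
        for (mode, direction), grp in df.groupby(["mode", "direction"], sort=True):
            grp = grp.sort_values("true_strain")
            curves.append(StressStrainCurve(
                mode=mode, direction=direction,
                strain=grp["true_strain"].to_numpy(),
                stress=grp["true_stress_MPa"].to_numpy(),
            ))
        return cls(curves, model=model, **kw)

    def fit(self, init=None, free: Sequence[str] | None = None,
            bounds: dict | None = None,
            compressibility: str = "incompressible") -> "CalibrationResult":
        res = fit_model(self.curves, self.model, init=init, free=free,
                        bounds=bounds, weights=self.weights,
                        compressibility=compressibility)
        return CalibrationResult(model=self, fit=res,
                                 compressibility=compressibility)


@dataclass
class CalibrationResult:
    """Fitted constants with diagnostics."""

    model: MaterialCalibration
    fit: FitResult
    compressibility: str = "incompressible"

    @property
    def params(self) -> AhyperParams | HyperfoamParams:
        return self.fit.params

    @property
    def rmse(self) -> float:
        return self.fit.total_rmse

    def predict(self, curve: StressStrainCurve) -> np.ndarray:
        return mode_response(self.params, curve.mode, curve.strain,
                             direction=curve.direction,
                             compressibility=self.compressibility).stress

    def summary(self) -> str:
        p = self.params
        lines = [
            f"Material calibration ({self.model.model})",
            "=" * 46,
            f"curves: {len(self.model.curves)}   points: {self.fit.n_points}   "
            f"converged: {self.fit.success}",
            f"free parameters: {', '.join(self.fit.free_names)}",
            "-" * 46,
        ]
        for name in p.names:
            tag = "*" if name in self.fit.free_names else " "
            lines.append(f"  {name:>6s}{tag} = {getattr(p, name):12.6g}")
        lines.append("-" * 46)
        for curve, rmse in zip(self.model.curves, self.fit.rmse_per_curve):
            lines.append(f"  RMSE {curve.mode}/{curve.direction}: {rmse:.4g} MPa")
        lines.append(f"  total RMSE: {self.fit.total_rmse:.4g} MPa")
        lines.append("(* fitted; others held at their initial values)")
        return "\n".join(lines)

    def plot_fit(self, path: str | None = None):
        """Data vs fitted response, one panel per curve."""
        import matplotlib

        if path is not None:
            matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        n = len(self.model.curves)
        fig, axes = plt.subplots(1, n, figsize=(4 * n, 3.2), squeeze=False)
        for ax, curve in zip(axes[0], self.model.curves):
            ax.plot(curve.strain, curve.stress, "k.", label="data")
            ax.plot(curve.strain, self.predict(curve), "r-", label="fit")
            ax.set_title(f"{curve.mode}\n{curve.direction}", fontsize=9)
            ax.set_xlabel("true strain")
            ax.set_ylabel("true stress [MPa]")
            ax.legend(fontsize=8)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=110)
            plt.close(fig)
            return None
        return fig
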