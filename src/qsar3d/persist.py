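"""Persisting a fitted model as a plain-text directory.

Layout: ``model.json`` (coefficients, centering, column metadata, grid and
field settings), one OpenDX std*coeff grid per field kind, ``summary.txt``
(the statistics report) and ``predictions.tsv`` (per-compound
actual/predicted/residual rows). Everything needed to featurise and predict
new aligned compounds reloads from ``model.json`` alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .contour import stdcoeff_field
from .dataset import CompoundRecord
from .fields import DescriptorMatrix, FieldCalculator, FieldGrid, GridSpec
from .griddata import write_dx
from .model import QSAR3DResults
from .pls import PLSModel

__all__ = ["save_results", "load_predictor", "FittedPredictor"]


def save_results(results: QSAR3DResults, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    m, X = results.model, results.matrix
    calc = X.calculator
    payload = {
        "coef": m.coef.tolist(),
        "x_mean": m.x_mean.tolist(),
        "y_mean": m.y_mean,
        "n_components": m.n_components,
        "col_kind": [str(k) for k in X.col_kind],
        "col_point": X.col_point.tolist(),
        "col_std": X.X.std(axis=0, ddof=1).tolist(),
        "block_scale": {str(k): float(v) for k, v in X.block_scale.items()},
        "weights": X.weights.tolist(),
        "grid": {"origin": list(calc.spec.origin), "spacing": calc.spec.spacing,
                 "dims": list(calc.spec.dims)},
        "kinds": list(calc.kinds),
        "alpha": calc.alpha,
        "dielectric": calc.dielectric,
        "dielectric_constant": calc.dielectric_constant,
        "truncation": calc.truncation,
        "train_ids": results.train_ids,
        "loo_q2": results.loo.q2,
        "r2": results.fit_stats.r2,
    }
    (directory / "model.json").write_text(json.dumps(payload, indent=1))
    (directory / "summary.txt").write_text(results.summary() + "\n")
    results.actual_vs_predicted().to_csv(directory / "predictions.tsv",
                                         sep="\t", index=False,
                                         float_format="%.6f")
    for kind in calc.kinds:
        values = stdcoeff_field(m, X, kind)
        write_dx(FieldGrid(spec=calc.spec, kind=f"stdcoeff_{kind}", values=values),
                 directory / f"stdcoeff_{kind}.dx")
    return directory


@dataclass
class FittedPredictor:
    """Reloaded model: featurises pre-aligned compounds and predicts."""

    model: PLSModel
    matrix: DescriptorMatrix  # zero-row carrier of column metadata
    loo_q2: float
    r2: float

    def predict(self, compounds: Sequence[CompoundRecord]) -> np.ndarray:
        return self.model.predict(self.matrix.transform(compounds))


def load_predictor(directory: str | Path) -> FittedPredictor:
    payload = json.loads((Path(directory) / "model.json").read_text())
    spec = GridSpec(origin=tuple(payload["grid"]["origin"]),
                    spacing=payload["grid"]["spacing"],
                    dims=tuple(payload["grid"]["dims"]))
    calc = FieldCalculator(spec=spec, kinds=tuple(payload["kinds"]),
                           alpha=payload["alpha"],
                           dielectric=payload["dielectric"],
                           dielectric_constant=payload["dielectric_constant"],
                           truncation=payload["truncation"])
    p = len(payload["coef"])
    matrix = DescriptorMatrix(
        ids=[], X=np.zeros((0, p)), calculator=calc,
        col_kind=np.array(payload["col_kind"]),
        col_point=np.array(payload["col_point"], dtype=int),
        block_scale=payload["block_scale"], dropped=[],
        weights=np.array(payload["weights"]))
    c = payload["n_components"]
    model = PLSModel(n_components=c,
                     x_mean=np.array(payload["x_mean"]),
                     y_mean=payload["y_mean"],
                     x_weights=np.zeros((p, c)), x_loadings=np.zeros((p, c)),
                     x_scores=np.zeros((0, c)), y_loadings=np.zeros(c),
                     coef=np.array(payload["coef"]),
                     training_ids=tuple(payload["train_ids"]))
    return FittedPredictor(model=model, matrix=matrix,
                           loo_q2=payload["loo_q2"], r2=payload["r2"])
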