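"""Model/Results front end tying the pipeline stages together.

:class:`QSAR3D` is constructed from compounds plus activities (or straight
from a synthetic scenario or from files), and ``fit()`` runs the full
field-QSAR workflow: scaffold alignment, grid-field generation, PLS with
leave-one-out component selection, optional region focusing, leave-group-out
and bootstrap diagnostics, and — when a test set is present — the external
validation suite with its acceptance gate. The returned
:class:`QSAR3DResults` carries every statistic, a ``summary()`` table, and
``predict()`` / ``contour_map()`` for downstream use.

Example
-------
>>> from qsar3d import QSAR3D, default_scenario
>>> res = QSAR3D.from_scenario(default_scenario(), method="comsia").fit()
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import pls as _pls
from .align import align_set
from .contour import ContourMap, contour_levels, stdcoeff_field
from .dataset import ActivityRecord, CompoundRecord, make_split
from .fields import DescriptorMatrix, build_descriptor_matrix, build_grid
from .pls import (BootstrapResult, CVResult, FitStatistics, PLSModel,
                  RegionFocusResult)
from .simulate import SCAFFOLD_PATTERN, ScenarioSpec, generate_set
from .validation import ExternalValidationReport, GTVerdict, external_validation, gt_gate

__all__ = ["QSAR3D", "QSAR3DResults"]


@dataclass
class QSAR3DResults:
    """Fitted-model container: estimates, diagnostics and reports."""

    model: PLSModel
    matrix: DescriptorMatrix  # training rows, final (possibly focused) columns
    train_ids: list[str]
    test_ids: list[str]
    y_train: np.ndarray
    y_test: np.ndarray | None
    onc: int
    q2_trace: list[float]
    loo: CVResult
    group: CVResult | None
    fit_stats: FitStatistics
    bootstrap: BootstrapResult | None
    focusing: RegionFocusResult | None
    external: ExternalValidationReport | None
    verdict: GTVerdict | None
    test_predictions: np.ndarray | None
    _parent: "QSAR3D" = field(repr=False, default=None)

    # -- downstream use -------------------------------------------------
    def predict(self, compounds: Sequence[CompoundRecord],
                align: bool = True) -> pd.DataFrame:
        """Predicted pIC50 for new compounds (aligned onto the template)."""
        if align and self._parent.pattern is not None:
            compounds = align_set(list(compounds) + [self._parent.template],
                                  self._parent.template.id, self._parent.pattern)[:-1]
        X = self.matrix.transform(compounds)
        pred = self.model.predict(X)
        return pd.DataFrame({"id": [c.id for c in compounds], "pred_pic50": pred})

    def contour_map(self, kind: str, favourable_pct: float = 80.0,
                    unfavourable_pct: float = 20.0) -> ContourMap:
        """Std*coeff contour map for one field kind."""
        values = stdcoeff_field(self.model, self.matrix, kind)
        return contour_levels(values, self.matrix.calculator.spec, kind=kind,
                              favourable_pct=favourable_pct,
                              unfavourable_pct=unfavourable_pct)

    def actual_vs_predicted(self) -> pd.DataFrame:
        """Per-compound actual/predicted/residual table (train + test)."""
        rows = []
        fitted = self.model.predict(self.matrix)
        for cid, act, pred in zip(self.train_ids, self.y_train, fitted):
            rows.append((cid, act, pred, pred - act, "train"))
        if self.test_predictions is not None:
            for cid, act, pred in zip(self.test_ids, self.y_test,
                                      self.test_predictions):
                rows.append((cid, act, pred, pred - act, "test"))
        return pd.DataFrame(rows, columns=["id", "actual", "predicted",
                                           "residual", "role"])

    # -- reporting ------------------------------------------------------
    def summary(self) -> str:
        s = self.fit_stats
        lines = [
            "3D-QSAR PLS model", "=" * 52,
            f"compounds (train/test)     {len(self.train_ids)}/{len(self.test_ids)}",
            f"descriptor columns         {self.matrix.n_columns}",
            f"field kinds                {', '.join(self.matrix.calculator.kinds)}",
            "",
            "PLS statistics",
            f"  LOO cross q2/SEP         {self.loo.q2:.3f}/{self.loo.sep:.3f}",
        ]
        if self.group is not None:
            lines.append(f"  Group cross q2/SEP       "
                         f"{self.group.q2:.3f}/{self.group.sep:.3f}")
        lines += [
            f"  Non-validated r2/SEE     {s.r2:.3f}/{s.see:.3f}",
            f"  F                        {s.f:.3f}",
        ]
        if self.bootstrap is not None:
            b = self.bootstrap
            lines += [f"  r2 bootstrap             {b.r2_mean:.3f}+/-{b.r2_sd:.3f}",
                      f"  S bootstrap              {b.see_mean:.3f}+/-{b.see_sd:.3f}"]
        lines.append(f"  Optimal components       {self.onc}")
        if self.focusing is not None:
            lines.append(f"  Region focusing q2       "
                         f"{self.focusing.q2_before:.3f} -> {self.focusing.q2_after:.3f}")
        lines.append("Field distribution%")
        for kind, frac in s.contributions.items():
            lines.append(f"  {kind:<24} {100 * frac:.1f}")
        if self.external is not None:
            e, v = self.external, self.verdict
            lines += [
                "", "External validation",
                f"  r2_pred                  {e.r2_pred:.3f}",
                f"  slope/intercept          {e.slope:.3f}/{e.intercept:.3f}",
                f"  correlation R            {e.r:.3f}",
                f"  k (through origin)       {e.k:.3f}",
                f"  r2_m                     {e.r2_m:.3f}",
                f"  (r2 - r2_0)/r2           {(e.r2 - e.r2_0) / e.r2:.3f}",
                f"  acceptance gate          {'PASS' if v.passed else 'FAIL'}",
            ]
            for name, (val, thr, ok) in v.criteria.items():
                lines.append(f"    {name:<20} {val: .3f}  {thr:<16} "
                             f"{'ok' if ok else 'FAIL'}")
        return "\n".join(lines)


class QSAR3D:
    """Field-based QSAR model over an aligned congeneric series.

    Parameters
    ----------
    compounds : the 3D structures (aligned, or alignable via *pattern*).
    activities : activity records carrying pIC50 and train/test roles.
    method : "comfa", "comsia" or "both" — which field family feeds PLS.
    pattern : scaffold SMARTS or atom-index list; ``None`` skips alignment
        (structures already share a frame).
    template_id : alignment template; defaults to the most active training
        compound.
    Remaining keywords mirror the stage defaults: grid spacing 2 A and
    margin 4 A, CoMSIA attenuation 0.3, CoMFA truncation 30 kcal/mol,
    component cap ``c_max``, the 10% component-acceptance rule, leave-group-
    out (10 groups x 25 repeats), bootstrap (B = 100) and optional region
    focusing with weight power ``focus_power``.
    """

    def __init__(self, compounds: Sequence[CompoundRecord],
                 activities: Sequence[ActivityRecord], *,
                 method: str = "comfa",
                 pattern: str | Sequence[int] | None = None,
                 template_id: str | None = None,
                 spacing: float = 2.0, margin: float = 4.0,
                 alpha: float = 0.3,
                 filter_sigma: dict[str, float] | None = None,
                 scaling: str = "block-standard",
                 c_max: int = 10, onc_threshold: float = 0.10,
                 region_focusing: bool = False, focus_power: float = 1.0,
                 cv_groups: int = 10, cv_repeats: int = 25,
                 bootstrap_B: int = 100,
                 run_group_cv: bool = True, run_bootstrap: bool = True,
                 seed: int = 0):
        self.compounds = list(compounds)
        self.activities = {a.id: a for a in activities}
        missing = [c.id for c in self.compounds if c.id not in self.activities]
        if missing:
            raise ValueError(f"no activity for compounds: {missing}")
        self.method = method
        self.pattern = pattern
        self.spacing, self.margin, self.alpha = spacing, margin, alpha
        self.filter_sigma, self.scaling = filter_sigma, scaling
        self.c_max, self.onc_threshold = c_max, onc_threshold
        self.region_focusing, self.focus_power = region_focusing, focus_power
        self.cv_groups, self.cv_repeats = cv_groups, cv_repeats
        self.bootstrap_B = bootstrap_B
        self.run_group_cv, self.run_bootstrap = run_group_cv, run_bootstrap
        self.seed = seed

        test_ids = {a.id for a in activities if a.role == "test"}
        self.split = make_split(list(activities), test_ids)
        train = [c for c in self.compounds if c.id in self.split.train]
        if template_id is None:
            template_id = max(train, key=lambda c: self.activities[c.id].pic50).id
        self.template = next(c for c in self.compounds if c.id == template_id)

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_files(cls, structures: str, activity_table: str,
                   charge_policy: str = "recompute", unit: str = "uM",
                   **kwargs) -> "QSAR3D":
        from .dataset import read_activity_table, read_compound_set
        compounds = read_compound_set(structures, charge_policy=charge_policy)
        activities = read_activity_table(activity_table, unit=unit)
        roles = {a.id: a.role for a in activities}
        for c in compounds:
            c.role = roles.get(c.id, "unassigned")
            if c.id in roles:
                c.activity = next(a.pic50 for a in activities if a.id == c.id)
        return cls(compounds, activities, **kwargs)

    @classmethod
    def from_scenario(cls, spec: ScenarioSpec, **kwargs) -> "QSAR3D":
        compounds, activities, truth = generate_set(spec)
        kwargs.setdefault("pattern", SCAFFOLD_PATTERN)
        obj = cls(compounds, activities, **kwargs)
        obj.truth = truth
        return obj

    # -- fitting --------------------------------------------------------
    def fit(self) -> QSAR3DResults:
        compounds = self.compounds
        if self.pattern is not None:
            compounds = align_set(compounds, self.template.id, self.pattern)
        grid = build_grid(compounds, spacing=self.spacing, margin=self.margin)
        matrix = build_descriptor_matrix(
            compounds, grid, fields=self.method,
            filter_sigma=self.filter_sigma, scaling=self.scaling,
            alpha=self.alpha)
        train_ids = [c.id for c in compounds if c.id in self.split.train]
        test_ids = [c.id for c in compounds if c.id in self.split.test]
        X_train = matrix.subset(train_ids)
        y_train = np.array([self.activities[i].pic50 for i in train_ids])

        onc, trace = _pls.select_onc(X_train, y_train, c_max=self.c_max,
                                     threshold=self.onc_threshold)
        model = _pls.fit_pls(X_train, y_train, onc)
        focusing = None
        if self.region_focusing:
            focusing = _pls.region_focus(X_train, y_train, model,
                                         weight_power=self.focus_power)
            X_train, model = focusing.matrix, focusing.model
            matrix = matrix.reweighted(focusing.weights)
        loo = _pls.loo_cv(X_train, y_train, onc)
        group = None
        if self.run_group_cv:
            group = _pls.group_cv(X_train, y_train, onc,
                                  groups=min(self.cv_groups, len(train_ids)),
                                  repeats=self.cv_repeats, seed=self.seed)
        boot = None
        if self.run_bootstrap:
            boot = _pls.bootstrap_fit(X_train, y_train, onc, B=self.bootstrap_B,
                                      seed=self.seed + 1)
        stats = _pls.model_summary(model, X_train, y_train)

        y_test = test_pred = external = verdict = None
        if len(test_ids) >= 3:
            y_test = np.array([self.activities[i].pic50 for i in test_ids])
            X_test = matrix.subset(test_ids)
            test_pred = model.predict(X_test)
            external = external_validation(y_test, test_pred,
                                           training_mean=float(y_train.mean()))
            verdict = gt_gate(external, q2=loo.q2, r2=stats.r2)
        return QSAR3DResults(
            model=model, matrix=X_train, train_ids=train_ids, test_ids=test_ids,
            y_train=y_train, y_test=y_test, onc=onc, q2_trace=trace, loo=loo,
            group=group, fit_stats=stats, bootstrap=boot, focusing=focusing,
            external=external, verdict=verdict, test_predictions=test_pred,
            _parent=self)
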