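"""Text serialization of fitted models.

A fitted estimator is written as a single JSON document holding the
constructor parameters, the resolved design (knots, orthogonalisation
transform, centering values, covariate levels), the parameter estimates and
the covariance matrix — everything needed to reload the fit and predict from
it.  The embedded rate table is stored as plain rows.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .lifetable import RateTable
from .models import CovariateDesign, FlexibleParametricModel, WeibullCureModel
from .splines import RestrictedCubicSpline

__all__ = ["save_model", "load_model", "model_to_dict", "model_from_dict"]


def _arr(a):
    return None if a is None else np.asarray(a).tolist()


def _spline_state(sp: RestrictedCubicSpline | None):
    if sp is None:
        return None
    return {
        "knots": _arr(sp.knots), "direction": sp.direction,
        "include_linear": sp.include_linear, "orthogonalize": sp.orthogonalize,
        "center_last_knot": sp.center_last_knot,
        "transform_r": _arr(sp.transform_r_), "center": _arr(sp.center_),
        "n_features_out": sp.n_features_out_,
    }


def _spline_restore(state):
    if state is None:
        return None
    sp = RestrictedCubicSpline(
        knots=np.asarray(state["knots"]), direction=state["direction"],
        include_linear=state["include_linear"],
        orthogonalize=state["orthogonalize"],
        center_last_knot=state["center_last_knot"])
    sp.knotset_ = __import__("flexcure.splines", fromlist=["KnotSet"]).KnotSet(
        np.asarray(state["knots"]))
    sp.transform_r_ = (None if state["transform_r"] is None
                       else np.asarray(state["transform_r"]))
    sp.center_ = np.asarray(state["center"])
    sp.n_features_out_ = state["n_features_out"]
    return sp


def _design_state(d: CovariateDesign):
    return {"columns": d.columns, "spec": d.spec_, "names": d.names_}


def _design_restore(state):
    d = CovariateDesign(state["columns"])
    d.spec_ = [(c, lv) for c, lv in state["spec"]]
    d.names_ = state["names"]
    return d


def _ratetable_state(rt: RateTable | None):
    if rt is None:
        return None
    f = rt.to_frame()
    return {"age": f["age"].tolist(), "year": f["year"].tolist(),
            "sex": f["sex"].astype(str).tolist(), "rate": f["rate"].tolist()}


def _ratetable_restore(state):
    return None if state is None else RateTable(pd.DataFrame(state))


_COMMON_FITTED = ("params_", "param_names_", "covariance_", "se_", "loglik_",
                  "n_", "n_events_", "converged_", "gradient_norm_",
                  "zero_time_shifted_")


def model_to_dict(model) -> dict:
    d = {"params": {k: v for k, v in model.get_params().items()
                    if k != "ratetable"},
         "ratetable": _ratetable_state(model.ratetable),
         "fitted": {}}
    for k in _COMMON_FITTED:
        v = getattr(model, k)
        d["fitted"][k] = _arr(v) if isinstance(v, np.ndarray) else v
    if isinstance(model, FlexibleParametricModel):
        d["class"] = "FlexibleParametricModel"
        d["params"]["knots"] = _arr(model.knots_)
        d["params"]["knots_scale"] = "log"
        d["fitted"].update({
            "knots_": _arr(model.knots_),
            "baseline_spline": _spline_state(model.baseline_spline_),
            "td_spline": _spline_state(model.td_spline_),
            "design": _design_state(model.design_),
            "td_design": _design_state(model.td_design_),
            "n_negative_excess_": model.n_negative_excess_,
        })
    elif isinstance(model, WeibullCureModel):
        d["class"] = "WeibullCureModel"
        d["fitted"].update({
            "blocks": list(model._blocks),
            "design": _design_state(model.design_),
            "scale_design": _design_state(model.scale_design_),
            "shape_design": _design_state(model.shape_design_),
        })
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    return d


def model_from_dict(d: dict):
    cls = {"FlexibleParametricModel": FlexibleParametricModel,
           "WeibullCureModel": WeibullCureModel}[d["class"]]
    model = cls(**d["params"])
    model.ratetable = _ratetable_restore(d["ratetable"])
    f = d["fitted"]
    for k in _COMMON_FITTED:
        v = f[k]
        if k in ("params_", "covariance_", "se_"):
            v = np.asarray(v)
        setattr(model, k, v)
    if cls is FlexibleParametricModel:
        model.knots_ = np.asarray(f["knots_"])
        model.baseline_spline_ = _spline_restore(f["baseline_spline"])
        model.td_spline_ = _spline_restore(f["td_spline"])
        model.design_ = _design_restore(f["design"])
        model.td_design_ = _design_restore(f["td_design"])
        model.n_negative_excess_ = f["n_negative_excess_"]
    else:
        model._blocks = tuple(f["blocks"])
        model.design_ = _design_restore(f["design"])
        model.scale_design_ = _design_restore(f["scale_design"])
        model.shape_design_ = _design_restore(f["shape_design"])
    return model


def save_model(model, path):
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1)


def load_model(path):
    with open(path) as fh:
        return model_from_dict(json.load(fh))
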