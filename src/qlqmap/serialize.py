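"""Plain-text (YAML) parameter files for fitted mapping models.

A parameter file is the distributable artifact of a mapping study —
the calculator a downstream analyst uses to convert QLQ-C30 scores to
utilities without refitting.  Files are self-describing: they carry the
method tag, the covariate lists and every coefficient labelled by name.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .aldvmm import AldvmmParams, AldvmmSpec
from .data import SchemaError
from .linear import LinearReParams
from .response import OrderedProbitDim, OrderedProbitSystem
from .tariff import DIMENSIONS

__all__ = ["save_model", "load_model"]


def _aldvmm_to_dict(spec: AldvmmSpec, params: AldvmmParams) -> dict:
    comp_cov = list(spec.component_covariates)
    memb_cov = list(spec.membership_covariates)
    components = []
    for c in range(spec.n_components):
        components.append({
            "coef": {n: float(v) for n, v in zip(comp_cov, params.beta[c])},
            "sigma": float(params.sigma[c]),
        })
    membership = [
        {n: float(v) for n, v in zip(memb_cov, params.gamma[c])}
        for c in range(spec.n_components - 1)
    ]
    return {
        "method": "aldvmm",
        "spec": {
            "n_components": spec.n_components,
            "component_covariates": comp_cov,
            "membership_covariates": memb_cov,
            "upper_threshold": spec.upper_threshold,
            "floor": spec.floor,
            "full_health": spec.full_health,
        },
        "components": components,
        "membership": membership,
    }


def _aldvmm_from_dict(doc: dict) -> tuple[AldvmmSpec, AldvmmParams]:
    try:
        s = doc["spec"]
        spec = AldvmmSpec(
            n_components=int(s["n_components"]),
            component_covariates=tuple(s["component_covariates"]),
            membership_covariates=tuple(s["membership_covariates"]),
            upper_threshold=float(s["upper_threshold"]),
            floor=float(s["floor"]),
            full_health=float(s["full_health"]),
        )
        beta = np.array([[c["coef"][n] for n in spec.component_covariates]
                         for c in doc["components"]], dtype=float)
        sigma = np.array([c["sigma"] for c in doc["components"]], dtype=float)
        gamma = np.array([[g[n] for n in spec.membership_covariates]
                          for g in doc.get("membership", [])], dtype=float)
        gamma = gamma.reshape(spec.n_components - 1,
                              len(spec.membership_covariates))
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"malformed aldvmm parameter file: {exc}") from exc
    if len(sigma) != spec.n_components:
        raise SchemaError("component count mismatch in parameter file")
    return spec, AldvmmParams(beta=beta, lnsigma=np.log(sigma), gamma=gamma)


def _linear_to_dict(params: LinearReParams) -> dict:
    return {
        "method": "linear",
        "coef": {k: float(v) for k, v in params.coef.items()},
        "re_var": float(params.re_var),
        "resid_var": float(params.resid_var),
    }


def _linear_from_dict(doc: dict) -> LinearReParams:
    try:
        return LinearReParams(coef={k: float(v) for k, v in doc["coef"].items()},
                              re_var=float(doc["re_var"]),
                              resid_var=float(doc["resid_var"]))
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"malformed linear parameter file: {exc}") from exc


def _response_to_dict(system: OrderedProbitSystem) -> dict:
    doc: dict = {
        "method": "response",
        "covariates": list(system.covariates),
        "dimensions": {},
    }
    for d in DIMENSIONS:
        dim = system.dims[d]
        doc["dimensions"][d] = {
            "coef": {k: float(v) for k, v in dim.coef.items()},
            "cut1": float(dim.cut1),
            "cut2": float(dim.cut2),
            "pinned": bool(dim.pinned),
        }
    if system.corr is not None:
        doc["corr"] = [[float(v) for v in row] for row in system.corr]
    return doc


def _response_from_dict(doc: dict) -> OrderedProbitSystem:
    try:
        dims = {}
        for d in DIMENSIONS:
            block = doc["dimensions"][d]
            dims[d] = OrderedProbitDim(
                dimension=d,
                coef={k: float(v) for k, v in block["coef"].items()},
                cut1=float(block["cut1"]),
                cut2=float(block["cut2"]),
                pinned=bool(block.get("pinned", False)),
            )
        corr = np.array(doc["corr"], dtype=float) if "corr" in doc else None
        return OrderedProbitSystem(dims=dims,
                                   covariates=tuple(doc["covariates"]),
                                   corr=corr)
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"malformed response parameter file: {exc}") from exc


def save_model(path: str | Path, model) -> None:
    """Write a fitted model to a YAML parameter file.

    ``model`` is ``(AldvmmSpec, AldvmmParams)``, a
    :class:`LinearReParams` or an :class:`OrderedProbitSystem`.
    """
    if isinstance(model, tuple) and isinstance(model[0], AldvmmSpec):
        doc = _aldvmm_to_dict(*model)
    elif isinstance(model, LinearReParams):
        doc = _linear_to_dict(model)
    elif isinstance(model, OrderedProbitSystem):
        doc = _response_to_dict(model)
    else:
        raise TypeError(f"cannot serialise {type(model)!r}")
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_model(path: str | Path):
    """Read a parameter file; returns the object matching its method tag."""
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise SchemaError(f"unreadable parameter file {path}: {exc}") from exc
    if not isinstance(doc, dict) or "method" not in doc:
        raise SchemaError(f"{path} is not a qlqmap parameter file")
    method = doc["method"]
    if method == "aldvmm":
        return _aldvmm_from_dict(doc)
    if method == "linear":
        return _linear_from_dict(doc)
    if method == "response":
        return _response_from_dict(doc)
    raise SchemaError(f"unknown method {method!r} in {path}")
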