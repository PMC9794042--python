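"""YAML/JSON serialization of parameters, population models and regimens."""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import yaml

from .errors import InputError
from .population import PopulationModel, ResidualError
from .structural import DualRouteParams, Regimen, weekly_regimen

_PARAM_FIELDS = (
    "CL", "V", "ka", "F", "F_rel", "D1", "D2",
    "zero_route_fraction_rule", "wk3_V_mult", "wk3_CL_mult",
)


def params_to_dict(p: DualRouteParams) -> dict:
    return {f: getattr(p, f) for f in _PARAM_FIELDS}


def params_from_dict(d: dict) -> DualRouteParams:
    return DualRouteParams(**{f: d[f] for f in _PARAM_FIELDS if f in d})


def pop_model_to_dict(pop: PopulationModel) -> dict:
    return {
        "drug": pop.drug,
        "theta": params_to_dict(pop.theta),
        "omega": dict(pop.omega),
        "sigma": {"kind": pop.sigma.kind, "prop": pop.sigma.prop, "add": pop.sigma.add},
    }


def pop_model_from_dict(d: dict) -> PopulationModel:
    sigma = d.get("sigma", {})
    return PopulationModel(
        drug=d["drug"],
        theta=params_from_dict(d["theta"]),
        omega=d.get("omega", {}),
        sigma=ResidualError(
            sigma.get("kind", "proportional"),
            float(sigma.get("prop", 0.0)),
            float(sigma.get("add", 0.0)),
        ),
    )


def regimen_to_dict(r: Regimen) -> dict:
    return {
        "n_weeks": r.n_weeks,
        "patch_free_h": r.patch_free_h,
        "events": [
            {"t_app": e.t_app, "amount": e.amount, "drug": e.drug} for e in r.events
        ],
    }


def regimen_from_dict(d: dict) -> Regimen:
    if "events" in d:
        from .structural import DoseEvent

        return Regimen(
            tuple(DoseEvent(**e) for e in d["events"]),
            int(d["n_weeks"]),
            float(d.get("patch_free_h", 168.0)),
        )
    return weekly_regimen(
        n_weeks=int(d.get("n_weeks", 12)),
        drugs=tuple(d.get("drugs", ("EE", "LNG"))),
        amounts_mg=d.get("amounts_mg"),
        patch_free_weeks=float(d.get("patch_free_weeks", 1.0)),
    )


def _load_structured(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise InputError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _dump_structured(obj: dict, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(obj, sort_keys=False))


def load_pop_model(path) -> PopulationModel:
    return pop_model_from_dict(_load_structured(path))


def save_pop_model(pop: PopulationModel, path) -> None:
    _dump_structured(pop_model_to_dict(pop), path)


def builtin_model_path(drug: str) -> Path:
    """Path to the packaged default (calibrated) model for a drug."""
    name = {"EE": "ee_model.yaml", "LNG": "lng_model.yaml"}.get(drug)
    if name is None:
        raise InputError(f"no builtin model for drug {drug!r}")
    return Path(resources.files("patchpk").joinpath("configs", name))


def default_model(drug: str) -> PopulationModel:
    return load_pop_model(builtin_model_path(drug))
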