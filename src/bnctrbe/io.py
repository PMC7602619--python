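"""CSV/JSON/YAML readers and writers for the package's tabular interfaces.

Formats
-------
* Stopping-power table: CSV with header ``energy_MeV,let_keV_um``.
* Mixed-field components: CSV with header ``label,dose_Gy,rbe_dsb,zbarF_Gy``.
* Survival data: CSV with header ``dose_Gy,surviving_fraction[,se]``.
* Depth profile: CSV with ``depth_cm,boron_ppm[,region]`` plus one dose
  column per component label.
* Run configuration: YAML mapping (scenario, tables, cell preset, reference).
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd
import yaml

from .pipeline import DepthDoseProfile
from .rmf import MixedField, RadiationComponent, RBEResult
from .survival import SurvivalDataset

__all__ = [
    "read_mixed_field",
    "write_mixed_field",
    "read_survival",
    "write_survival",
    "read_depth_profile",
    "rbe_result_to_dict",
    "write_result_json",
    "read_config",
]

_PROFILE_META = ("depth_cm", "boron_ppm", "region")


def read_mixed_field(path) -> MixedField:
    df = pd.read_csv(path, comment="#")
    comps = [
        RadiationComponent(label=str(r.label), dose=float(r.dose_Gy),
                           rbe_dsb=float(r.rbe_dsb), zbarF=float(r.zbarF_Gy))
        for r in df.itertuples(index=False)
    ]
    return MixedField(comps)


def write_mixed_field(field: MixedField, path) -> None:
    pd.DataFrame(
        [{"label": c.label, "dose_Gy": c.dose, "rbe_dsb": c.rbe_dsb,
          "zbarF_Gy": c.zbarF} for c in field]
    ).to_csv(path, index=False)


def read_survival(path, **metadata) -> SurvivalDataset:
    df = pd.read_csv(path, comment="#")
    se = df["se"].to_numpy() if "se" in df.columns else None
    return SurvivalDataset(
        doses=df["dose_Gy"].to_numpy(),
        fractions=df["surviving_fraction"].to_numpy(),
        se=se, metadata=metadata)


def write_survival(data: SurvivalDataset, path) -> None:
    cols = {"dose_Gy": data.doses, "surviving_fraction": data.fractions}
    if data.se is not None:
        cols["se"] = data.se
    pd.DataFrame(cols).to_csv(path, index=False)


def read_depth_profile(path) -> DepthDoseProfile:
    df = pd.read_csv(path, comment="#")
    dose_cols = [c for c in df.columns if c not in _PROFILE_META]
    return DepthDoseProfile(
        depths=df["depth_cm"].to_numpy(),
        doses=df[dose_cols].reset_index(drop=True),
        boron_ppm=df["boron_ppm"].to_numpy(),
        region_labels=(df["region"].tolist() if "region" in df.columns
                       else None),
    )


def rbe_result_to_dict(res: RBEResult) -> dict:
    d = dataclasses.asdict(res)
    d["lq"] = {"alpha_Gy^-1": res.lq.alpha, "beta_Gy^-2": res.lq.beta}
    return d


def write_result_json(obj, path) -> None:
    """Serialize a result (dataclass, dict, DataFrame) to JSON."""
    if isinstance(obj, pd.DataFrame):
        payload = obj.to_dict(orient="records")
    elif dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        payload = dataclasses.asdict(obj)
    else:
        payload = obj

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default)
        fh.write("\n")


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
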