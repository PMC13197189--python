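"""Model configuration files, shipped fixtures and result serialization.

Config files are YAML with explicit units in key names (j couplings in Hz as
`j_couplings_hz`, relaxation times as `t1_s`, fields in tesla): ultralow-field
work mixes Hz, rad/s and microtesla, and unit bugs are the dominant failure
mode.  A model file holds a `substrate` and a `complex` section (the complex
lists the substrate nuclei first, then the two hydrides) plus `kinetics`.

Results are written as long-format CSV with a JSON sidecar recording the
matrix dimensions, configuration weights and solver settings, so every run
is reproducible from its sidecar alone.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .sabre_engine import SabreModel
from .spin_system import (
    GAMMA_RAD_PER_T,
    EquivalenceGroup,
    Nucleus,
    SpinSystem,
    SpinSystemError,
    validate_system,
)
from .zqc import matrix_dimensions

__all__ = [
    "load_model",
    "save_model",
    "write_results",
    "acetonitrile_15N13C2",
    "butyronitrile_15N13C4",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("acetonitrile_15N13C2", "butyronitrile_15N13C4")


def _parse_system(section: dict, where: str) -> SpinSystem:
    try:
        raw_nuclei = section["nuclei"]
    except KeyError:
        raise SpinSystemError(f"{where}: missing 'nuclei'") from None
    nuclei = []
    for entry in raw_nuclei:
        isotope = entry.get("isotope")
        gamma = entry.get("gamma_rad_per_t")
        if gamma is None:
            if isotope not in GAMMA_RAD_PER_T:
                raise SpinSystemError(
                    f"{where}: unknown isotope {isotope!r} for nucleus "
                    f"{entry.get('label')!r} and no explicit gamma_rad_per_t"
                )
            gamma = GAMMA_RAD_PER_T[isotope]
        nuclei.append(
            Nucleus(
                label=str(entry["label"]),
                isotope=str(isotope),
                gamma=float(gamma),
                spin=float(entry.get("spin", 0.5)),
                t1=float(entry["t1_s"]) if entry.get("t1_s") is not None else None,
                shift_ppm=float(entry.get("shift_ppm", 0.0)),
            )
        )
    j_table = {}
    for row in section.get("j_couplings_hz", []):
        if len(row) != 3:
            raise SpinSystemError(f"{where}: J entry must be [label, label, Hz]: {row}")
        j_table[(str(row[0]), str(row[1]))] = float(row[2])
    groups = tuple(
        EquivalenceGroup(
            name=str(g["name"]),
            members=tuple(str(m) for m in g["members"]),
            t1=float(g["t1_s"]) if g.get("t1_s") is not None else None,
        )
        for g in section.get("groups", [])
    )
    return validate_system(SpinSystem(nuclei=tuple(nuclei), j_table=j_table, groups=groups))


def load_model(path_or_dict) -> SabreModel:
    """Load and validate a SABRE model from a YAML file (or parsed dict)."""
    if isinstance(path_or_dict, dict):
        doc = path_or_dict
        name = doc.get("name", "")
    else:
        path = Path(path_or_dict)
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        name = doc.get("name", path.stem)
    for key in ("substrate", "complex", "kinetics"):
        if key not in doc:
            raise SpinSystemError(f"model file is missing the {key!r} section")
    kin = doc["kinetics"]
    return SabreModel(
        substrate=_parse_system(doc["substrate"], "substrate"),
        complex=_parse_system(doc["complex"], "complex"),
        kd=float(kin["kd_per_s"]),
        cs=float(kin["complex_to_substrate_ratio"]),
        name=str(name),
    )


def _dump_system(system: SpinSystem) -> dict:
    return {
        "nuclei": [
            {
                "label": n.label,
                "isotope": n.isotope,
                "gamma_rad_per_t": n.gamma,
                "spin": n.spin,
                **({"t1_s": n.t1} if n.t1 is not None else {}),
                **({"shift_ppm": n.shift_ppm} if n.shift_ppm else {}),
            }
            for n in system.nuclei
        ],
        "j_couplings_hz": [[a, b, j] for (a, b), j in sorted(system.j_table.items())],
        "groups": [
            {
                "name": g.name,
                "members": list(g.members),
                **({"t1_s": g.t1} if g.t1 is not None else {}),
            }
            for g in system.groups
        ],
    }


def save_model(model: SabreModel, path) -> Path:
    """Write a model back to YAML; round-trips all couplings bit-exact."""
    doc = {
        "name": model.name,
        "kinetics": {"kd_per_s": model.kd, "complex_to_substrate_ratio": model.cs},
        "substrate": _dump_system(model.substrate),
        "complex": _dump_system(model.complex),
    }
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


def write_results(df: pd.DataFrame, path, sidecar: dict | None = None) -> Path:
    """Long-format CSV plus a JSON sidecar (<path>.json) with run metadata."""
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.12g")
    meta = {"zulfsabre_version": __version__, "columns": list(df.columns)}
    if sidecar:
        meta.update(sidecar)
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    return path


def model_sidecar(model: SabreModel, **extra) -> dict:
    """Standard metadata block: dimensions per representation and weights."""
    dims = matrix_dimensions(model.substrate, model.complex)
    return {
        "model": model.name,
        "kd_per_s": model.kd,
        "complex_to_substrate_ratio": model.cs,
        "dim_full": dims["full"],
        "dim_k_reduced_max": dims["k_reduced_max"],
        "dim_zqc_max": dims["zqc_max"],
        "configs": [
            {"config": c["config"], "weight": str(c["weight"]), "zqc": c["zqc"]}
            for c in dims["per_config"]
        ],
        **extra,
    }


def _load_fixture(name: str) -> SabreModel:
    ref = resources.files("zulfsabre").joinpath(f"data/{name}.yaml")
    with resources.as_file(ref) as path:
        return load_model(path)


def acetonitrile_15N13C2() -> SabreModel:
    """Six-spin [15N,13C2]acetonitrile SABRE model (8 spins in the complex).

    The shipped J/T1 values are a representative (synthetic) parameter set
    for this isotopologue; see the YAML header for details.
    """
    return _load_fixture("acetonitrile_15N13C2")


def butyronitrile_15N13C4() -> SabreModel:
    """Twelve-spin [15N,13C4]butyronitrile SABRE model (14 spins in the complex)."""
    return _load_fixture("butyronitrile_15N13C4")
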