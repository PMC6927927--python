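"""Configuration, fixtures, and result serialization.

Ties the scenario modules into reproducible runs: named presets for the
four device ring configurations, the 37 degC Nitinol wire calibration and
the aortic wall fit; YAML/JSON config loading with schema and unit
validation; a run manifest that echoes every resolved parameter (including
defaults that fill gaps the source data does not dimension); and writers
for JSON scalars, CSV curves, HDF5 state snapshots and VTK polylines.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .forming import RingConfig
from .nitinol import NitinolParams
from .vessel import AORTA_COEFFS, AORTA_D1, AORTA_DENSITY

__all__ = [
    "PRESET_RINGS",
    "PRESET_MATERIALS",
    "PRESET_VESSELS",
    "RunManifest",
    "load_config",
    "write_results",
    "save_state_h5",
    "load_state_h5",
    "write_vtk_polyline",
]

#: the four device ring-bundle fixtures (wire diameter, ring mean diameter,
#: number of turns), mm
PRESET_RINGS: dict[str, RingConfig] = {
    "ring1": RingConfig(0.180, 27.02, 10, name="ring1"),
    "ring2": RingConfig(0.160, 33.16, 8, name="ring2"),
    "ring3": RingConfig(0.220, 39.25, 14, name="ring3"),
    "ring4": RingConfig(0.200, 48.09, 9, name="ring4"),
}

PRESET_MATERIALS: dict[str, NitinolParams] = {
    "nitinol_37C": NitinolParams(),
}

PRESET_VESSELS: dict[str, dict] = {
    "aorta_labrosse_67_77": dict(
        c=list(AORTA_COEFFS), D1=AORTA_D1, thickness=2.0,
        length_factor=2.0, density=AORTA_DENSITY,
    ),
}

_EXPECTED_UNITS = {
    "d_wire": "mm", "D_ring": "mm", "length": "mm", "thickness": "mm",
    "catheter_diameter": "mm", "inner_tube_diameter": "mm",
    "string_length": "mm",
    "string_stiffness_ref": "N/mm", "k_pen": "N/mm",
    "P_d": "mmHg", "P_s": "mmHg", "P_m": "mmHg",
    "E_A": "MPa", "E_M": "MPa",
    "sigma_LS": "MPa", "sigma_LE": "MPa", "sigma_US": "MPa",
    "sigma_UE": "MPa", "sigma_CS": "MPa",
}

_KNOWN_SECTIONS = {"ring", "nitinol", "vessel", "saddle", "deploy", "units", "seed"}

_KNOWN_KEYS = {
    "ring": {"preset", "d_wire", "D_ring", "n_turns", "include_prestrain", "name"},
    "nitinol": {"preset", "E_A", "nu_A", "E_M", "nu_M", "eps_L", "sigma_LS",
                "sigma_LE", "sigma_US", "sigma_UE", "sigma_CS", "density",
                "compression_scale"},
    "vessel": {"preset", "c", "c1", "c2", "c3", "c4", "c5", "c6", "D1",
               "thickness", "length_factor", "density", "oversize_pct"},
    "saddle": {"string_stiffness_ref", "string_length", "oversize_high",
               "oversize_low", "pull_overshoot", "n_cycles", "n_inc_pull",
               "n_inc_cycle"},
    "deploy": {"catheter_diameter", "inner_tube_diameter", "oversize_pct",
               "P_d", "P_s", "mu_vessel", "mu_sheath", "k_pen",
               "perturb_scale", "seed", "band_width", "n_inc_compact",
               "n_inc_deploy", "n_pulse_cycles"},
}


class ConfigError(ValueError):
    pass


def _resolve_value(section: str, key: str, value):
    """Scalars pass through; {value, unit} dicts are unit-checked."""
    if isinstance(value, dict) and set(value) >= {"value", "unit"}:
        expected = _EXPECTED_UNITS.get(key)
        if expected is not None and value["unit"] != expected:
            raise ConfigError(
                f"{section}.{key}: unit '{value['unit']}' not supported; "
                f"expected {expected}")
        return value["value"]
    return value


def load_config(path: str | Path) -> dict:
    """Load and validate a scenario configuration (YAML or JSON).

    Presets (``ring1``..``ring4``, ``nitinol_37C``,
    ``aorta_labrosse_67_77``) resolve by name; unknown sections or keys are
    rejected with a message naming the offending key.  Returns a dict with
    instantiated ``RingConfig`` / ``NitinolParams`` objects plus plain
    parameter dicts for the scenario sections.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _KNOWN_SECTIONS
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")

    units = raw.get("units", {})
    for qty, unit in units.items():
        allowed = {"length": "mm", "force": "N", "stress": "MPa",
                   "pressure": "mmHg"}
        if qty not in allowed:
            raise ConfigError(f"units.{qty}: unknown quantity")
        if unit != allowed[qty]:
            raise ConfigError(
                f"units.{qty}: '{unit}' not supported; expected {allowed[qty]}")

    out: dict = {"seed": int(raw.get("seed", 0))}
    for section in ("ring", "nitinol", "vessel", "saddle", "deploy"):
        if section not in raw:
            continue
        block = raw[section]
        if isinstance(block, str):
            block = {"preset": block}
        if not isinstance(block, dict):
            raise ConfigError(f"section '{section}' must be a mapping or preset name")
        bad = set(block) - _KNOWN_KEYS[section]
        if bad:
            raise ConfigError(f"{section}: unknown key(s) {sorted(bad)}")
        block = {k: _resolve_value(section, k, v) for k, v in block.items()}

        if section == "ring":
            if "preset" in block:
                cfg = PRESET_RINGS[block.pop("preset")]
                cfg = dataclasses.replace(cfg, **block) if block else cfg
            else:
                cfg = RingConfig(**block)
            out["ring"] = cfg
        elif section == "nitinol":
            if "preset" in block:
                mat = PRESET_MATERIALS[block.pop("preset")]
                mat = dataclasses.replace(mat, **block) if block else mat
            else:
                mat = NitinolParams(**block)
            out["nitinol"] = mat
        elif section == "vessel":
            if "preset" in block:
                base = dict(PRESET_VESSELS[block.pop("preset")])
                base.update(block)
                block = base
            if any(f"c{i}" in block for i in range(1, 7)):
                block["c"] = [block.pop(f"c{i}") for i in range(1, 7)]
            out["vessel"] = block
        else:
            out[section] = block
    return out


@dataclass
class RunManifest:
    """Reproducibility record written next to every result."""

    command: str
    config: dict
    seed: int
    version: str = __version__
    units: dict = field(default_factory=lambda: dict(
        length="mm", force="N", stress="MPa", pressure="mmHg"))
    defaults_filled: list = field(default_factory=list)
    solver_notes: list = field(default_factory=list)

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)
        return json.dumps(dataclasses.asdict(self), indent=2, default=enc)


def write_results(out_dir: str | Path, scalars: dict, manifest: RunManifest,
                  curves: dict | None = None) -> dict[str, Path]:
    """Write result JSON + manifest (+ CSV curves); returns written paths.

    Deterministic: identical configs and versions produce byte-identical
    scalar/curve files (no timestamps inside).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def enc(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    p = out_dir / "result.json"
    p.write_text(json.dumps(scalars, indent=2, default=enc, sort_keys=True) + "\n")
    paths["result"] = p
    p = out_dir / "manifest.json"
    p.write_text(manifest.to_json() + "\n")
    paths["manifest"] = p
    if curves:
        for name, df in curves.items():
            p = out_dir / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
    return paths


def save_state_h5(model, path: str | Path) -> None:
    """Snapshot a beam model's kinematic + material state to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["version"] = __version__
        f.attrs["turn_mult"] = model.turn_mult
        f.attrs["r_wire"] = model.section.r_wire
        if hasattr(model, "r_bundle"):
            f.attrs["r_bundle"] = model.r_bundle
        if hasattr(model, "ring_config"):
            rc = model.ring_config
            f.attrs["ring"] = json.dumps(dataclasses.asdict(rc))
        for name in ("X0", "u", "Rn", "conn", "L0", "c_ref",
                     "xi", "eps_tr", "eps_fib", "sig_fib",
                     "tare_a", "tare_b"):
            f.create_dataset(name, data=getattr(model, name))


def load_state_h5(path: str | Path):
    """Rebuild a beam model from an HDF5 snapshot."""
    import h5py

    from . import beam_fe as bf

    with h5py.File(path, "r") as f:
        sec = bf.WireSection(r_wire=float(f.attrs["r_wire"]))
        model = bf.BeamModel(
            f["X0"][()], f["Rn"][()], f["conn"][()], sec, f["L0"][()],
            c_ref=f["c_ref"][()], turn_mult=int(f.attrs["turn_mult"]))
        for name in ("u", "xi", "eps_tr", "eps_fib", "sig_fib",
                     "tare_a", "tare_b"):
            setattr(model, name, f[name][()])
        if "r_bundle" in f.attrs:
            model.r_bundle = float(f.attrs["r_bundle"])
        if "ring" in f.attrs:
            model.ring_config = RingConfig(**json.loads(f.attrs["ring"]))
            n = model.n_el
            model.quarter_nodes = {"B": 0, "A": n // 4, "D": n // 2,
                                   "C": 3 * n // 4}
            bf.weld_close(model, n, 0)
    return model


def write_vtk_polyline(model, path: str | Path, point_data: dict | None = None) -> None:
    """Write the wire centerline as a legacy-ASCII VTK polyline.

    ``point_data`` maps field names to per-node scalar arrays (the maximum
    fiber strain per adjacent element is always included).
    """
    x = model.X0 + model.u
    n = x.shape[0]
    eps_node = np.zeros(n)
    cnt = np.zeros(n)
    emax = np.abs(model.eps_fib).max(axis=1)
    for e, (a, b) in enumerate(model.conn):
        eps_node[[a, b]] += emax[e]
        cnt[[a, b]] += 1.0
    eps_node /= np.maximum(cnt, 1.0)
    fields = {"max_fiber_strain": eps_node}
    if point_data:
        fields.update(point_data)

    lines = [
        "# vtk DataFile Version 3.0",
        "ring stent wire centerline",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} double",
    ]
    lines += [f"{p[0]:.8e} {p[1]:.8e} {p[2]:.8e}" for p in x]
    m = model.conn.shape[0]
    lines.append(f"LINES {m} {3 * m}")
    lines += [f"2 {a} {b}" for a, b in model.conn]
    lines.append(f"POINT_DATA {n}")
    for name, arr in fields.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.8e}" for v in np.asarray(arr, float)]
    Path(path).write_text("\n".join(lines) + "\n")
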