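"""Readers and writers for the package's text formats: peak / shift /
isotherm CSV dialects (with ``#key=value`` metadata lines), restraint JSON,
and XYZ / PDB conformer output.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .langmuir import GAMMA0_WATER_BUFFER, IsothermCurve, surface_pressure
from .model import Conformer
from .noe import PEAK_COLUMNS, DistanceRestraint, restraints_to_records

__all__ = [
    "read_peak_csv", "write_peak_csv",
    "read_shift_csv", "write_shift_csv",
    "read_isotherm_csv", "write_isotherm_csv",
    "write_restraints_json", "read_restraints_json",
    "write_conformer", "read_xyz",
]


def _split_metadata(path) -> tuple[dict[str, str], str]:
    meta: dict[str, str] = {}
    body: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            if "=" in line:
                k, _, v = line[1:].partition("=")
                meta[k.strip()] = v.strip()
        else:
            body.append(line)
    return meta, "\n".join(body)


def _write_with_metadata(path, df: pd.DataFrame, meta: dict) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            if v is not None and v != "":
                fh.write(f"#{k}={v}\n")
        df.to_csv(fh, index=False)


def read_peak_csv(path) -> pd.DataFrame:
    """Cross-peak table: group_a,group_b,volume,spectrum,environment,
    overlap_flag. Malformed rows are rejected with their row number
    (1-based, excluding header/metadata)."""
    meta, body = _split_metadata(path)
    df = pd.read_csv(_io.StringIO(body))
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    df["overlap_flag"] = df["overlap_flag"].astype(bool)
    bad = df.index[~(df["volume"] > 0)]
    if len(bad):
        raise ValueError(
            f"{path}: nonpositive volume in data row(s) "
            f"{[int(i) + 1 for i in bad]}")
    df.attrs.update(meta)
    return df


def write_peak_csv(path, peaks: pd.DataFrame, **meta) -> None:
    _write_with_metadata(path, peaks[PEAK_COLUMNS], meta)


def read_shift_csv(path) -> pd.DataFrame:
    """Shift table: proton,environment,delta_ppm."""
    meta, body = _split_metadata(path)
    df = pd.read_csv(_io.StringIO(body))
    missing = [c for c in ("proton", "environment", "delta_ppm")
               if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df["delta_ppm"].isna().any():
        bad = [int(i) + 1 for i in df.index[df["delta_ppm"].isna()]]
        raise ValueError(f"{path}: missing delta_ppm in data row(s) {bad}")
    df.attrs.update(meta)
    return df


def write_shift_csv(path, shifts: pd.DataFrame, **meta) -> None:
    _write_with_metadata(path, shifts[["proton", "environment", "delta_ppm"]],
                         meta)


def read_isotherm_csv(path) -> list[IsothermCurve]:
    """Isotherm replicates: ``replicate,area_A2,pressure_mN_m`` (or
    ``gamma_mN_m``), with ``#gamma0=``, ``#x=``, ``#lipid=``, ``#additive=``
    metadata lines."""
    meta, body = _split_metadata(path)
    df = pd.read_csv(_io.StringIO(body))
    gamma0 = float(meta.get("gamma0", GAMMA0_WATER_BUFFER))
    x = float(meta.get("x", 1.0))
    lipid = meta.get("lipid", "")
    additive = meta.get("additive", "")
    if "pressure_mN_m" in df.columns:
        pres = df["pressure_mN_m"].to_numpy(float)
    elif "gamma_mN_m" in df.columns:
        pres = surface_pressure(gamma0, df["gamma_mN_m"].to_numpy(float))
    else:
        raise ValueError(f"{path}: need a pressure_mN_m or gamma_mN_m column")
    if "area_A2" not in df.columns:
        raise ValueError(f"{path}: missing area_A2 column")
    if not (df["area_A2"] > 0).all():
        bad = [int(i) + 1 for i in df.index[~(df["area_A2"] > 0)]]
        raise ValueError(f"{path}: nonpositive area in data row(s) {bad}")
    rep = df["replicate"] if "replicate" in df.columns else pd.Series(
        0, index=df.index)
    curves = []
    for r in rep.unique():
        m = rep == r
        curves.append(IsothermCurve(df.loc[m, "area_A2"].to_numpy(float),
                                    np.asarray(pres)[m.to_numpy()],
                                    gamma0, x, lipid, additive))
    return curves


def write_isotherm_csv(path, replicates: pd.DataFrame,
                       gamma0: float = GAMMA0_WATER_BUFFER, x: float = 1.0,
                       lipid: str = "", additive: str = "") -> None:
    _write_with_metadata(
        path, replicates[["replicate", "area_A2", "pressure_mN_m"]],
        {"gamma0": gamma0, "x": x, "lipid": lipid, "additive": additive})


def write_restraints_json(path, restraints: list[DistanceRestraint],
                          excluded=None) -> None:
    payload = {"restraints": restraints_to_records(restraints),
               "excluded": [
                   {"pair": list(e["pair"]), "class": e.get("class"),
                    "reason": e.get("reason", "flagged")}
                   for e in (excluded or [])]}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_restraints_json(path) -> list[DistanceRestraint]:
    payload = json.loads(Path(path).read_text())
    return [DistanceRestraint(tuple(r["pair"]), float(r["lower_A"]),
                              (None if r["upper_A"] is None
                               else float(r["upper_A"])),
                              r.get("class"), source=r.get("source", ""))
            for r in payload["restraints"]]


def write_conformer(conformer: Conformer, path, fmt: str | None = None) -> None:
    """Write a conformer as XYZ or minimal PDB (HETATM + CONECT).

    ``fmt`` defaults from the file suffix. Coordinates to 3 decimals.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    topo = conformer.topology
    if fmt == "xyz":
        lines = [str(topo.n_atoms),
                 f"{topo.headgroup}-{topo.n_units} idealized conformer"]
        for el, (x, y, z) in zip(topo.elements, conformer.coords):
            lines.append(f"{el:<2s} {x:10.3f} {y:10.3f} {z:10.3f}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "pdb":
        lines = []
        for i, (el, name, (x, y, z)) in enumerate(
                zip(topo.elements, topo.atom_names, conformer.coords), 1):
            nm = name[:4]
            lines.append(
                f"HETATM{i:5d} {nm:<4s} UNL A   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {el:>2s}")
        neigh: dict[int, list[int]] = {}
        for a, b in topo.bonds():
            neigh.setdefault(a, []).append(b)
            neigh.setdefault(b, []).append(a)
        for a in sorted(neigh):
            partners = "".join(f"{b + 1:5d}" for b in sorted(neigh[a]))
            lines.append(f"CONECT{a + 1:5d}{partners}")
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown conformer format {fmt!r}")


def read_xyz(path) -> tuple[list[str], np.ndarray]:
    """Elements and coordinates from an XYZ file."""
    lines = Path(path).read_text().splitlines()
    n = int(lines[0])
    elements, coords = [], []
    for line in lines[2:2 + n]:
        el, x, y, z = line.split()
        elements.append(el)
        coords.append((float(x), float(y), float(z)))
    return elements, np.array(coords)
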