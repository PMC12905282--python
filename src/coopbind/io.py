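"""Readers and writers for the four input formats plus run configuration.

Formats: ITC per-injection heat tables (CSV), Sparky-style amide peak lists
(tab-separated), 3-column ATSAS-style scattering curves (.dat) and single- or
multi-page TIFF images.  Writers and readers round-trip up to float
formatting.
"""

from __future__ import annotations

import csv
import json
import re
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .csp import Peak, PeakList
from .imaging import CellImage
from .itc import Isotherm, TitrationProtocol
from .saxs import ScatteringCurve

__all__ = [
    "ParseError",
    "read_itc_csv",
    "write_itc_csv",
    "read_protocol",
    "write_protocol",
    "read_peaklist",
    "write_peaklist",
    "read_saxs_dat",
    "write_saxs_dat",
    "read_tiff",
    "write_tiff",
    "load_config",
    "DEFAULT_CONFIG",
]

KCAL_PER_UCAL = 1e-9


class ParseError(ValueError):
    """Malformed input file; message names the file, line and column."""


# ---------------------------------------------------------------------------
# ITC


def read_itc_csv(path: str | Path, protocol: TitrationProtocol) -> Isotherm:
    """Read a per-injection heat table.

    Required columns: ``injection_index``, ``dV_uL`` and one of ``q_ucal`` /
    ``q_kcal_per_mol``; optional ``sigma`` (same units as the heat column).
    Cell/syringe concentrations come from the protocol, which also fixes the
    dilution convention for the molar-ratio axis.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        required = {"injection_index", "dV_uL"}
        if not required <= set(header):
            raise ParseError(
                f"{path}: line 1: header must contain {sorted(required)}"
            )
        if "q_ucal" in header:
            q_col, per_mol = "q_ucal", False
        elif "q_kcal_per_mol" in header:
            q_col, per_mol = "q_kcal_per_mol", True
        else:
            raise ParseError(f"{path}: line 1: no heat column (q_ucal or q_kcal_per_mol)")
        idx = {name: header.index(name) for name in header}
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(header)} fields, got {len(row)}"
                )
            try:
                rows.append(
                    (
                        int(row[idx["injection_index"]]),
                        float(row[idx["dV_uL"]]),
                        float(row[idx[q_col]]),
                        float(row[idx["sigma"]]) if "sigma" in idx and row[idx["sigma"]].strip() else None,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    if not rows:
        raise ParseError(f"{path}: no data rows")
    if len(rows) != protocol.n_injections:
        raise ParseError(
            f"{path}: {len(rows)} rows but protocol declares "
            f"{protocol.n_injections} injections"
        )
    dV = np.array([r[1] for r in rows]) * 1e-6  # uL -> L
    if not np.allclose(dV, protocol.injection_volumes, rtol=1e-6):
        raise ParseError(f"{path}: injection volumes disagree with protocol")
    moles = protocol.syringe_concentration * dV
    q = np.array([r[2] for r in rows])
    sig = np.array([r[3] if r[3] is not None else np.nan for r in rows])
    if per_mol:
        q = q * moles
        sig = sig * moles
    else:
        q = q * KCAL_PER_UCAL
        sig = sig * KCAL_PER_UCAL
    sigma = None if np.all(np.isnan(sig)) else np.where(np.isnan(sig), 0.0, sig)
    Mt, Xt = protocol.cell_concentrations()
    Q = np.cumsum(q)  # reconstructed without the displaced-volume terms
    return Isotherm(
        cumulative_volume=np.cumsum(protocol.injection_volumes),
        molar_ratio=Xt / Mt,
        Q=Q,
        q=q,
        sigma=sigma,
        injected_moles=moles,
    )


def write_itc_csv(isotherm: Isotherm, path: str | Path) -> None:
    """Write per-injection heats in microcalories (q_ucal)."""
    path = Path(path)
    dV_uL = np.diff(np.concatenate([[0.0], isotherm.cumulative_volume])) / 1e-6
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = ["injection_index", "dV_uL", "q_ucal"]
        has_sigma = isotherm.sigma is not None
        if has_sigma:
            header.append("sigma")
        writer.writerow(header)
        for i in range(isotherm.n_injections):
            row = [
                str(i + 1),
                f"{dV_uL[i]:.10g}",
                f"{isotherm.q[i] / KCAL_PER_UCAL:.12g}",
            ]
            if has_sigma:
                row.append(f"{isotherm.sigma[i] / KCAL_PER_UCAL:.12g}")
            writer.writerow(row)


def read_protocol(path: str | Path) -> TitrationProtocol:
    """Titration protocol from a YAML config block."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    known = {
        "cell_volume_mL",
        "cell_concentration_uM",
        "syringe_concentration_uM",
        "injection_volumes_uL",
        "temperature_K",
    }
    unknown = set(cfg) - known
    if unknown:
        raise ParseError(f"{path}: unknown protocol keys {sorted(unknown)}")
    return TitrationProtocol(
        cell_volume=float(cfg["cell_volume_mL"]) * 1e-3,
        cell_concentration=float(cfg["cell_concentration_uM"]) * 1e-6,
        syringe_concentration=float(cfg["syringe_concentration_uM"]) * 1e-6,
        injection_volumes=np.asarray(cfg["injection_volumes_uL"], dtype=float) * 1e-6,
        temperature=float(cfg.get("temperature_K", 298.15)),
    )


def write_protocol(protocol: TitrationProtocol, path: str | Path) -> None:
    cfg = {
        "cell_volume_mL": protocol.cell_volume * 1e3,
        "cell_concentration_uM": protocol.cell_concentration * 1e6,
        "syringe_concentration_uM": protocol.syringe_concentration * 1e6,
        "injection_volumes_uL": (protocol.injection_volumes * 1e6).tolist(),
        "temperature_K": protocol.temperature,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh)


# ---------------------------------------------------------------------------
# Peak lists

_ASSIGNMENT = re.compile(r"^([A-Za-z])(\d+)N-H$")


def read_peaklist(path: str | Path, condition: str | None = None) -> PeakList:
    """Sparky-style peak list: Assignment, w1 (15N ppm), w2 (1H ppm), Height.

    Tab- or whitespace-separated; the Height column may be missing.  Lines
    starting with '#' and the 'Assignment' header line are skipped.
    """
    path = Path(path)
    plist = PeakList(condition=condition or path.stem)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("assignment"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: need at least 3 columns, got {len(fields)}"
                )
            m = _ASSIGNMENT.match(fields[0])
            if m is None:
                raise ParseError(
                    f"{path}: line {lineno}: column 1: bad assignment {fields[0]!r}"
                )
            try:
                w1 = float(fields[1])  # 15N
                w2 = float(fields[2])  # 1H
                height = float(fields[3]) if len(fields) > 3 and fields[3].strip() else None
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            plist.add(
                Peak(
                    residue_id=int(m.group(2)),
                    residue_name=m.group(1).upper(),
                    deltaH=w2,
                    deltaN=w1,
                    height=height,
                )
            )
    return plist


def write_peaklist(plist: PeakList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("Assignment\tw1\tw2\tHeight\n")
        for rid in plist:
            pk = plist[rid]
            if not np.isfinite(pk.deltaH):
                continue  # absent peaks are simply not in the spectrum
            name = (pk.residue_name or "X")[0]
            height = "" if pk.height is None else f"{pk.height:.12g}"
            fh.write(f"{name}{rid}N-H\t{pk.deltaN:.12g}\t{pk.deltaH:.12g}\t{height}\n")


# ---------------------------------------------------------------------------
# SAXS curves


def read_saxs_dat(path: str | Path) -> ScatteringCurve:
    """3-column whitespace text (q, I, sigma); '#' comments preserved."""
    path = Path(path)
    comments: list[str] = []
    q, I, s = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                comments.append(stripped.lstrip("# "))
                continue
            fields = stripped.split()
            if len(fields) < 2:
                raise ParseError(f"{path}: line {lineno}: need q and I columns")
            try:
                q.append(float(fields[0]))
                I.append(float(fields[1]))
                s.append(float(fields[2]) if len(fields) > 2 else np.nan)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    if not q:
        raise ParseError(f"{path}: no data rows")
    sigma = np.array(s)
    sigma_arr = None if np.all(np.isnan(sigma)) else sigma
    try:
        return ScatteringCurve(
            np.array(q), np.array(I), sigma_arr, {"comments": comments}
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_saxs_dat(curve: ScatteringCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in curve.metadata.get("comments", []):
            fh.write(f"# {c}\n")
        for i in range(curve.n_points):
            s = curve.sigma[i] if curve.sigma is not None else np.nan
            fh.write(f"{curve.q[i]:.10e} {curve.I[i]:.10e} {s:.10e}\n")


# ---------------------------------------------------------------------------
# Images


def read_tiff(path: str | Path, channel_map: dict[str, int]) -> CellImage:
    """Multi-page TIFF with a name -> page-index map."""
    pages = tifffile.imread(str(path))
    if pages.ndim == 2:
        pages = pages[None, ...]
    channels = {}
    for name, idx in channel_map.items():
        if idx >= pages.shape[0]:
            raise ParseError(f"{path}: channel {name!r} wants page {idx}, "
                             f"file has {pages.shape[0]}")
        channels[name] = np.asarray(pages[idx], dtype=float)
    return CellImage(channels)


def write_tiff(image: CellImage, path: str | Path, order: list[str] | None = None) -> None:
    order = order or sorted(image.channels)
    stack = np.stack([image.channels[ch].astype(np.float32) for ch in order])
    tifffile.imwrite(str(path), stack, photometric="minisblack")


# ---------------------------------------------------------------------------
# Run configuration

DEFAULT_CONFIG: dict = {
    "itc": {
        "model": "two_sets",
        "exclude_first": False,
        "temperature_K": 298.15,
    },
    "csp": {"robust": False},
    "saxs": {
        "qmax_rg_limit": 1.3,
        "dmax_step_A": 2.0,
        "vc_calibration": "protein",
        "frame_rg_tolerance": 0.05,
    },
    "imaging": {
        "spot_area_min_px2": 20.0,
        "spot_area_max_px2": 300.0,
        "spot_ratio_max": 0.3,
        "min_spots": 10,
        "threshold_nmads": 6.0,
        "per_cell": False,
    },
    "seed": 0,
    "log_level": "INFO",
}


def load_config(path: str | Path | None = None) -> dict:
    """Defaults overlaid with a YAML file; unknown keys are rejected."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    _merge(cfg, user, [], Path(path))
    return cfg


def _merge(base: dict, user: dict, crumbs: list[str], path: Path) -> None:
    for key, value in user.items():
        if key not in base:
            where = ".".join(crumbs + [str(key)])
            raise ParseError(f"{path}: unknown config key {where!r}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            _merge(base[key], value, crumbs + [str(key)], path)
        else:
            base[key] = value
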