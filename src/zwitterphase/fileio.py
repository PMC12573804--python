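"""Readers and writers for the pipeline's text dialects.

Window series travel as GROMACS-style .xvg pull files ('#'/'@' header
lines, two whitespace-separated columns: sample index, z in nm); frames as
an extended-XYZ-like block format; PMFs and FES grids as TSV; copolymer
tables as CSV with '#' metadata header rows. All writers and readers are
mutually inverse on their own output at the stored precision.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ROLES, FrameSet, UmbrellaWindow
from .errors import ParseError, SchemaError
from .phase import CopolymerSeries
from .wham import PMFProfile

_FLOAT_FMT = "%.8g"


# ---------------------------------------------------------------------------
# .xvg window series
# ---------------------------------------------------------------------------

def write_window_series(path, window: UmbrellaWindow) -> None:
    """Write one window's z series as a two-column .xvg file."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# umbrella window {window.index}\n")
        fh.write(f"# center_nm {window.center!r} k_z {window.k_z!r} k_r {window.k_r!r}\n")
        fh.write('@ title "Pull coordinate"\n')
        fh.write('@ xaxis label "sample"\n')
        fh.write('@ yaxis label "z (nm)"\n')
        for i, z in enumerate(window.series):
            fh.write(f"{i}\t{z:.10g}\n")


def read_window_series(path, meta: UmbrellaWindow) -> UmbrellaWindow:
    """Read a two-column .xvg series into a copy of ``meta``.

    '#' and '@' lines are ignored; column 2 is the reaction coordinate in
    nm, kept in file order. A non-numeric body row raises :class:`ParseError`
    naming the line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"window series file not found: {path}")
    values = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "@")):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"expected two columns in {path.name}", line=lineno)
            try:
                values.append(float(parts[1]))
            except ValueError:
                raise ParseError(
                    f"non-numeric value {parts[1]!r} in {path.name}", line=lineno
                ) from None
    return UmbrellaWindow(
        index=meta.index, center=meta.center, k_z=meta.k_z, k_r=meta.k_r,
        series=np.asarray(values), r_series=meta.r_series,
        bias_offset=meta.bias_offset,
    )


def write_window_metadata(path, windows: list[UmbrellaWindow],
                          filenames: list[str]) -> None:
    """TSV manifest (index, center, k_z, k_r, file) for a window collection."""
    pd.DataFrame({
        "index": [w.index for w in windows],
        "center_nm": [w.center for w in windows],
        "k_z": [w.k_z for w in windows],
        "k_r": [w.k_r for w in windows],
        "file": filenames,
    }).to_csv(path, sep="\t", index=False)


def read_window_collection(meta_path) -> list[UmbrellaWindow]:
    """Read a manifest plus the .xvg files it names (relative to it)."""
    meta_path = Path(meta_path)
    df = pd.read_csv(meta_path, sep="\t", float_precision="round_trip")
    windows = []
    for row in df.itertuples(index=False):
        meta = UmbrellaWindow(index=int(row.index), center=float(row.center_nm),
                              k_z=float(row.k_z), k_r=float(row.k_r))
        windows.append(read_window_series(meta_path.parent / row.file, meta))
    return windows


# ---------------------------------------------------------------------------
# extended-XYZ-like frames
# ---------------------------------------------------------------------------

def write_frames(path, frames: FrameSet) -> None:
    """Write a frame set as extended-XYZ-like text blocks.

    Each block: atom count, a comment line carrying frame id, window, z,
    V_z, V_r (kJ/mol) and the optional ground-truth label, then one
    ``role x y z`` line per labelled atom (nm).
    """
    with Path(path).open("w") as fh:
        for j in range(len(frames)):
            fh.write(f"{len(frames.roles)}\n")
            comment = (
                f"frame={frames.frame_ids[j]} window={frames.window_index[j]} "
                f"z={frames.z[j]:.8g} V_z={frames.v_z[j]:.8g} V_r={frames.v_r[j]:.8g}"
            )
            if frames.labels is not None:
                comment += f" label={frames.labels[j]}"
            fh.write(comment + "\n")
            for a, role in enumerate(frames.roles):
                x, y, z = frames.coords[j, a]
                fh.write(f"{role} {x:.8g} {y:.8g} {z:.8g}\n")


def _parse_comment(line: str, block: int) -> dict:
    fields = {}
    for token in line.split():
        if "=" not in token:
            raise ParseError(f"malformed frame comment token {token!r} in block {block}")
        key, val = token.split("=", 1)
        fields[key] = val
    for required in ("frame", "window", "z", "V_z", "V_r"):
        if required not in fields:
            raise SchemaError(f"frame block {block} comment missing {required!r}")
    return fields


def read_frames(path) -> FrameSet:
    """Read an extended-XYZ-like frame file written by :func:`write_frames`.

    A frame with a missing or duplicated atom role raises
    :class:`SchemaError` naming the frame id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"frame file not found: {path}")
    lines = path.read_text().splitlines()
    coords, win, zc, vz, vr, labels, ids = [], [], [], [], [], [], []
    pos, block = 0, 0
    any_label = False
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError:
            raise ParseError(f"expected atom count, got {lines[pos]!r}", line=pos + 1) from None
        meta = _parse_comment(lines[pos + 1], block)
        fid = meta["frame"]
        atom_lines = lines[pos + 2: pos + 2 + natoms]
        if len(atom_lines) < natoms:
            raise SchemaError(f"frame {fid}: truncated block ({len(atom_lines)}/{natoms} atoms)")
        seen = {}
        for k, al in enumerate(atom_lines):
            parts = al.split()
            if len(parts) != 4:
                raise ParseError(f"bad atom line in frame {fid}", line=pos + 3 + k)
            role = parts[0]
            if role in seen:
                raise SchemaError(f"frame {fid}: duplicate atom role {role!r}")
            seen[role] = [float(v) for v in parts[1:]]
        missing = [r for r in ROLES if r not in seen]
        if missing:
            raise SchemaError(f"frame {fid}: missing atom roles {missing}")
        coords.append([seen[r] for r in ROLES])
        win.append(int(meta["window"]))
        zc.append(float(meta["z"]))
        vz.append(float(meta["V_z"]))
        vr.append(float(meta["V_r"]))
        ids.append(int(fid))
        if "label" in meta:
            any_label = True
            labels.append(meta["label"])
        else:
            labels.append("")
        pos += 2 + natoms
        block += 1
    if not coords:
        raise ParseError(f"no frames found in {path}")
    return FrameSet(
        coords=np.asarray(coords), window_index=np.asarray(win),
        z=np.asarray(zc), v_z=np.asarray(vz), v_r=np.asarray(vr),
        labels=np.asarray(labels) if any_label else None,
        frame_ids=np.asarray(ids),
    )


# ---------------------------------------------------------------------------
# PMF / alignment / FES tables
# ---------------------------------------------------------------------------

def write_pmf_table(path, pmf: PMFProfile) -> None:
    """PMF as TSV: z_nm, F_kBT, SE_kBT, mask (1 = unpopulated bin)."""
    se = pmf.se if pmf.se is not None else np.full_like(pmf.f, np.nan)
    pd.DataFrame({
        "z_nm": pmf.z, "F_kBT": pmf.f, "SE_kBT": se,
        "mask": pmf.mask.astype(int),
    }).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_pmf_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PMF table not found: {path}")
    return pd.read_csv(path, sep="\t")


def write_alignment_constants(path, pmf: PMFProfile,
                              windows: list[UmbrellaWindow]) -> None:
    """Per-window alignment constants F_i (kBT) as TSV."""
    pd.DataFrame({
        "window": [w.index for w in windows],
        "F_i_kBT": pmf.f_i,
    }).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_alignment_constants(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["window"].astype(int), df["F_i_kBT"].astype(float)))


def write_ensemble(path, pmf: PMFProfile) -> None:
    """Bootstrap ensemble members as TSV (one column per member)."""
    if pmf.ensemble is None:
        raise ValueError("PMF profile carries no bootstrap ensemble")
    cols = {"z_nm": pmf.z}
    for b, member in enumerate(pmf.ensemble):
        cols[f"member_{b}"] = member
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_fes_grid(path, fes) -> None:
    """FES grid as long-format TSV (pc1, pc2, G_kBT, mask)."""
    xx, yy = np.meshgrid(fes.grid_x, fes.grid_y, indexing="ij")
    pd.DataFrame({
        "pc1": xx.ravel(), "pc2": yy.ravel(),
        "G_kBT": fes.g.ravel(), "mask": fes.mask.ravel().astype(int),
    }).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_minima(path, minima) -> None:
    pd.DataFrame({
        "pc1": [m.pc1 for m in minima],
        "pc2": [m.pc2 for m in minima],
        "G_kBT": [m.g for m in minima],
        "n_members": [m.member_frames.size for m in minima],
    }).to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# copolymer tables and reports
# ---------------------------------------------------------------------------

def read_copolymer_table(path) -> CopolymerSeries:
    """CSV with '#' metadata header rows and columns label, f_sticker,
    cs_max, tcp (tcp optional)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"copolymer table not found: {path}")
    metadata = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, val = line.lstrip("#").split(":", 1)
                metadata[key.strip()] = val.strip()
    df = pd.read_csv(path, comment="#")
    return CopolymerSeries(data=df, metadata=metadata or None)


def write_copolymer_table(path, series: CopolymerSeries) -> None:
    with Path(path).open("w") as fh:
        for key, val in (series.metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        series.data.to_csv(fh, index=False)


def write_fit_report(path, fits: dict) -> None:
    """Fit report as JSON-style key-value text."""
    payload = {}
    for name, fit in fits.items():
        payload[name] = {
            "slope": fit.slope, "intercept": fit.intercept,
            "stderr_slope": fit.stderr_slope, "resid_se": fit.resid_se,
            "r_squared": fit.r_squared, "n": fit.n, "transform": fit.transform,
        }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
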