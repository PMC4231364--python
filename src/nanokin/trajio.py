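"""Multi-model PDB and XYZ trajectory readers/writers.

Dialect: coordinate records only (ATOM), one MODEL/ENDMDL block per frame
(a file without MODEL records is a single frame); alternate locations other
than blank or 'A' are dropped; insertion codes are kept as part of the
residue id ("52A").  Coordinates round-trip to the PDB fixed precision of
0.001 Angstrom.  XYZ files are frame-per-block with the frame time stored
on the comment line ("t= <ns> ns") when written by this package.
"""
from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .trajectory import Trajectory

__all__ = ["read_pdb", "write_pdb", "read_xyz", "write_xyz"]


def _format_atom_name(name: str) -> str:
    # PDB columns 13-16: names up to 3 chars start in column 14
    return f" {name:<3s}" if len(name) < 4 else name[:4]


def _split_resid(resid: str) -> tuple[int, str]:
    m = re.fullmatch(r"(-?\d+)([A-Za-z]?)", resid)
    if not m:
        raise ValidationError(f"residue_ids: cannot serialize {resid!r} to PDB")
    return int(m.group(1)), m.group(2)


def write_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file."""
    lines: list[str] = []
    for f in range(traj.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        for i in range(traj.n_atoms):
            num, icode = _split_resid(traj.residue_ids[i])
            x, y, z = traj.coords[f, i]
            if max(abs(x), abs(y), abs(z)) >= 10000:
                raise ValidationError(
                    f"coords: |coordinate| >= 10000 A at atom {i} does not fit PDB fields"
                )
            lines.append(
                f"ATOM  {min(i + 1, 99999):5d} {_format_atom_name(traj.atom_names[i])}"
                f" {traj.residue_names[i]:>3.3s} {traj.chains[i][:1] or 'A'}"
                f"{num:4d}{icode or ' '}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdb(path: str | Path, dt_ns: float = 0.1) -> Trajectory:
    """Read a multi-model PDB file into a Trajectory.

    PDB carries no time axis; frame times are assigned as frame_index*dt_ns.
    """
    frames: list[list[tuple[float, float, float]]] = []
    meta: list[tuple[str, str, str, str]] | None = None
    cur_coords: list[tuple[float, float, float]] = []
    cur_meta: list[tuple[str, str, str, str]] = []
    in_model = False
    saw_model = False

    def _close_frame() -> None:
        nonlocal meta
        if not cur_coords:
            return
        if meta is None:
            meta = list(cur_meta)
        elif cur_meta != meta:
            raise ValidationError(
                f"{path}: atom records differ between models "
                f"({len(cur_meta)} atoms vs {len(meta)})"
            )
        frames.append(list(cur_coords))

    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            in_model = saw_model = True
            cur_coords, cur_meta = [], []
        elif rec == "ENDMDL":
            _close_frame()
            in_model = False
        elif rec == "ATOM  ":
            altloc = line[16]
            if altloc not in (" ", "A"):
                continue
            try:
                name = line[12:16].strip()
                resname = line[17:20].strip()
                chain = line[21].strip() or "A"
                resid = line[22:26].strip() + line[26].strip()
                xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
            except (ValueError, IndexError) as exc:
                raise ValidationError(f"{path}:{lineno}: malformed ATOM record") from exc
            cur_coords.append(xyz)
            cur_meta.append((name, resid, resname, chain))
    if not saw_model or (in_model and cur_coords):
        _close_frame()

    if not frames:
        raise ValidationError(f"{path}: no ATOM coordinates found")
    assert meta is not None
    return Trajectory(
        coords=np.asarray(frames, dtype=float),
        frame_times=np.arange(len(frames)) * dt_ns,
        atom_names=[m[0] for m in meta],
        residue_ids=[m[1] for m in meta],
        residue_names=[m[2] for m in meta],
        chains=[m[3] for m in meta],
    )


def write_xyz(traj: Trajectory, path: str | Path) -> None:
    """Write a frame-per-block XYZ file (atom name, x, y, z per line)."""
    lines: list[str] = []
    for f in range(traj.n_frames):
        lines.append(str(traj.n_atoms))
        lines.append(f"t= {traj.frame_times[f]:.6f} ns")
        for i in range(traj.n_atoms):
            x, y, z = traj.coords[f, i]
            lines.append(f"{traj.atom_names[i]:<4s} {x:15.8f} {y:15.8f} {z:15.8f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path: str | Path, dt_ns: float = 0.1) -> Trajectory:
    """Read a frame-per-block XYZ file.

    Frame times are parsed from comment lines of the form "t= <value> ns"
    when present, otherwise assigned as frame_index*dt_ns.  XYZ carries no
    residue information; atoms are numbered as one residue each.
    """
    text = Path(path).read_text().splitlines()
    frames: list[np.ndarray] = []
    times: list[float] = []
    names: list[str] | None = None
    pos = 0
    while pos < len(text):
        if not text[pos].strip():
            pos += 1
            continue
        try:
            n = int(text[pos].strip())
        except ValueError as exc:
            raise ValidationError(f"{path}:{pos + 1}: expected atom count") from exc
        comment = text[pos + 1] if pos + 1 < len(text) else ""
        m = re.search(r"t=\s*([-\d.eE+]+)", comment)
        times.append(float(m.group(1)) if m else len(frames) * dt_ns)
        block = text[pos + 2 : pos + 2 + n]
        if len(block) < n:
            raise ValidationError(f"{path}: truncated frame at line {pos + 1}")
        cur_names, coords = [], []
        for lineno, line in enumerate(block, start=pos + 3):
            parts = line.split()
            if len(parts) < 4:
                raise ValidationError(f"{path}:{lineno}: expected 'name x y z'")
            cur_names.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        if names is None:
            names = cur_names
        elif names != cur_names:
            raise ValidationError(f"{path}: atom names differ between frames")
        frames.append(np.asarray(coords))
        pos += 2 + n
    if not frames:
        raise ValidationError(f"{path}: no frames found")
    assert names is not None
    n = len(names)
    return Trajectory(
        coords=np.asarray(frames),
        frame_times=np.asarray(times),
        atom_names=names,
        residue_ids=[str(i + 1) for i in range(n)],
        residue_names=["UNK"] * n,
        chains=["A"] * n,
    )
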