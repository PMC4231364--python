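"""Trajectory stability metrics: Kabsch superposition, RMSD, RMSF, distances.

Implements the standard operators used to read conformational stability off
an atomic trajectory of a protein: least-squares optimal rigid-body
superposition (Kabsch, via SVD with reflection suppression), backbone RMSD
time courses relative to a reference frame, per-residue C-alpha RMSF about
the superposed mean structure, and inter-atom distance time series such as
the catalytic His-Ser distance of a serine hydrolase (triad Ser-His-Asp;
an increasing His N(eps2) to Ser O(gamma) distance signals loss of
active-site integrity).

Coordinates are Angstrom internally; every series can be reported in nm.
"""
from __future__ import annotations

import fnmatch
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError, require

__all__ = [
    "Trajectory",
    "Superposition",
    "RMSFProfile",
    "BACKBONE_ATOMS",
    "select_atoms",
    "kabsch_superpose",
    "rmsd",
    "rmsd_timeseries",
    "rmsf_per_residue",
    "distance_timeseries",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")
_NM_PER_ANGSTROM = 0.1


@dataclass
class Trajectory:
    """Frames x atoms x 3 coordinates with atom/residue labels.

    residue_ids are strings so insertion codes survive (e.g. "52A"); they
    follow the numbering of the source file.
    """

    coords: np.ndarray  # (n_frames, n_atoms, 3), Angstrom
    frame_times: np.ndarray  # ns, increasing
    atom_names: list[str]
    residue_ids: list[str]
    residue_names: list[str]
    chains: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        require(self.coords.ndim == 3 and self.coords.shape[2] == 3,
                "coords", "must have shape (n_frames, n_atoms, 3)")
        require(np.isfinite(self.coords).all(), "coords", "must be finite")
        require(self.frame_times.shape == (self.coords.shape[0],),
                "frame_times", "must have one entry per frame")
        require(bool(np.all(np.diff(self.frame_times) > 0)) or self.n_frames == 1,
                "frame_times", "must be strictly increasing")
        n = self.n_atoms
        for name, lst in (
            ("atom_names", self.atom_names),
            ("residue_ids", self.residue_ids),
            ("residue_names", self.residue_names),
            ("chains", self.chains),
        ):
            require(len(lst) == n, name, f"must have one entry per atom ({n})")

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[1])

    def atom_label(self, i: int) -> str:
        return f"{self.chains[i]}:{self.residue_ids[i]}:{self.atom_names[i]}"


@dataclass
class Superposition:
    """Optimal rigid-body map x -> rotation @ x + translation (Angstrom)."""

    rotation: np.ndarray  # 3x3 proper orthogonal
    translation: np.ndarray  # 3-vector
    rmsd: float  # over the atoms used for the superposition

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass
class RMSFProfile:
    """Per-residue root-mean-square fluctuation about the mean structure."""

    residue_ids: list[str]
    rmsf: np.ndarray  # one value per residue, Angstrom (or nm on request)
    selection: str
    units: str = "angstrom"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"residue_id": self.residue_ids, f"rmsf_{'nm' if self.units == 'nm' else 'A'}": self.rmsf}
        )


# ---------------------------------------------------------------------------
# selection mini-language
# ---------------------------------------------------------------------------

def select_atoms(traj: Trajectory, selection: str) -> np.ndarray:
    """Resolve a selection to atom indices.

    Named selections: "all", "backbone" (atoms N, CA, C, O), "CA"/"calpha".
    Otherwise "chain:resid:atomname" with fnmatch wildcards per field, e.g.
    "A:208:NE2" or "*:13?:CA".
    """
    sel = selection.strip()
    low = sel.lower()
    if low == "all":
        return np.arange(traj.n_atoms)
    if low == "backbone":
        return np.flatnonzero(np.isin(traj.atom_names, BACKBONE_ATOMS))
    if low in ("ca", "calpha", "c-alpha"):
        return np.flatnonzero(np.asarray(traj.atom_names) == "CA")
    parts = sel.split(":")
    if len(parts) != 3:
        raise ValidationError(
            f"selection: {sel!r} is not a named selection or 'chain:resid:atomname'"
        )
    chain_pat, res_pat, name_pat = (p.strip() or "*" for p in parts)
    idx = [
        i
        for i in range(traj.n_atoms)
        if fnmatch.fnmatchcase(traj.chains[i], chain_pat)
        and fnmatch.fnmatchcase(traj.residue_ids[i], res_pat)
        and fnmatch.fnmatchcase(traj.atom_names[i], name_pat)
    ]
    return np.asarray(idx, dtype=int)


def _resolve_single_atom(traj: Trajectory, spec: str) -> int:
    idx = select_atoms(traj, spec)
    if idx.size == 1:
        return int(idx[0])
    if idx.size == 0:
        raise ValidationError(f"atom spec {spec!r} matched no atoms")
    cands = ", ".join(traj.atom_label(i) for i in idx[:10])
    raise ValidationError(
        f"atom spec {spec!r} is ambiguous: matched {idx.size} atoms ({cands}"
        + (", ..." if idx.size > 10 else "") + ")"
    )


# ---------------------------------------------------------------------------
# superposition and metrics
# ---------------------------------------------------------------------------

def _check_superposable(ref_centered: np.ndarray) -> None:
    # collinear reference: rotation about the line is unconstrained
    s = np.linalg.svd(ref_centered, compute_uv=False)
    if s.size < 2 or s[1] <= 1e-8 * max(s[0], 1.0):
        raise ValidationError(
            "selection: reference atoms are collinear or coincident; "
            "superposition is not well-posed"
        )


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> Superposition:
    """Least-squares optimal proper rotation + translation mapping mobile
    onto reference (both (n, 3), n >= 3 non-collinear points).

    SVD of the cross-covariance with a sign correction on the smallest
    singular direction suppresses reflections, so the rotation is always
    proper (det = +1).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    require(P.ndim == 2 and P.shape[1] == 3, "mobile", "must be (n, 3)")
    require(P.shape == Q.shape, "reference", "must match mobile's shape")
    require(P.shape[0] >= 3, "mobile", "need >= 3 atoms for superposition")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    _check_superposable(Q0)
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = P0 @ R.T - Q0
    value = float(np.sqrt((diff**2).sum() / P.shape[0]))
    return Superposition(rotation=R, translation=t, rmsd=value)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (no superposition) root-mean-square deviation between two
    coordinate sets."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    require(a.shape == b.shape, "b", "must match a's shape")
    return float(np.sqrt(((a - b) ** 2).sum(axis=-1).mean()))


def _unit_scale(units: str) -> float:
    if units in ("angstrom", "A", "Å"):
        return 1.0
    if units == "nm":
        return _NM_PER_ANGSTROM
    raise ValidationError(f"units: unknown unit {units!r} (use 'angstrom' or 'nm')")


def rmsd_timeseries(
    traj: Trajectory,
    reference_frame: int = 0,
    selection: str = "backbone",
    units: str = "angstrom",
) -> pd.DataFrame:
    """Per-frame RMSD to a reference frame after per-frame superposition.

    Each frame is optimally superposed onto the reference over the selected
    atoms; the RMSD is computed over the same selection.  Columns: time_ns,
    rmsd (in the requested units).
    """
    idx = select_atoms(traj, selection)
    if idx.size == 0:
        raise ValidationError(f"selection {selection!r} matched no atoms")
    ref = traj.coords[reference_frame][idx]
    scale = _unit_scale(units)
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        values[f] = kabsch_superpose(traj.coords[f][idx], ref).rmsd
    return pd.DataFrame({"time_ns": traj.frame_times, "rmsd": values * scale})


def rmsf_per_residue(
    traj: Trajectory,
    selection: str = "CA",
    units: str = "angstrom",
    align_selection: str | None = None,
) -> RMSFProfile:
    """Per-residue RMSF of the selected atoms about the mean structure.

    Two superposition passes: frames are superposed onto the raw mean of the
    alignment atoms, the mean is recomputed from the superposed frames, and
    frames are superposed again onto the refined mean.  RMSF_i is the root
    mean (over frames) squared displacement of atom i from its time-averaged
    position; atoms of the same residue are averaged.  align_selection
    defaults to the reported selection; pass a rigid subset to keep mobile
    atoms out of the alignment.
    """
    idx = select_atoms(traj, selection)
    if idx.size == 0:
        raise ValidationError(f"selection {selection!r} matched no atoms")
    aidx = idx if align_selection is None else select_atoms(traj, align_selection)
    if aidx.size == 0:
        raise ValidationError(f"selection {align_selection!r} matched no atoms")
    X = traj.coords[:, idx, :]
    A = traj.coords[:, aidx, :]

    amean = A.mean(axis=0)
    for _ in range(2):
        aligned = np.empty_like(X)
        aligned_A = np.empty_like(A)
        for f in range(X.shape[0]):
            sup = kabsch_superpose(A[f], amean)
            aligned[f] = sup.apply(X[f])
            aligned_A[f] = sup.apply(A[f])
        amean = aligned_A.mean(axis=0)
    mean = aligned.mean(axis=0)
    sq = ((aligned - mean) ** 2).sum(axis=2)  # (frames, atoms)
    atom_rmsf = np.sqrt(sq.mean(axis=0))

    scale = _unit_scale(units)
    res_keys: list[str] = []
    per_res: dict[str, list[float]] = {}
    for j, i in enumerate(idx):
        key = f"{traj.chains[i]}:{traj.residue_ids[i]}"
        if key not in per_res:
            per_res[key] = []
            res_keys.append(key)
        per_res[key].append(atom_rmsf[j])
    values = np.array([np.mean(per_res[k]) for k in res_keys]) * scale
    return RMSFProfile(
        residue_ids=res_keys,
        rmsf=values,
        selection=selection,
        units="nm" if scale != 1.0 else "angstrom",
    )


def distance_timeseries(
    traj: Trajectory, atom_spec_a: str, atom_spec_b: str, units: str = "angstrom"
) -> pd.DataFrame:
    """Euclidean distance between two uniquely specified atoms per frame.

    Default use: the catalytic His-Ser distance (His NE2 to Ser OG),
    e.g. distance_timeseries(traj, "A:208:NE2", "A:130:OG").
    Columns: time_ns, distance.
    """
    ia = _resolve_single_atom(traj, atom_spec_a)
    ib = _resolve_single_atom(traj, atom_spec_b)
    scale = _unit_scale(units)
    d = np.linalg.norm(traj.coords[:, ia, :] - traj.coords[:, ib, :], axis=1)
    return pd.DataFrame({"time_ns": traj.frame_times, "distance": d * scale})
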