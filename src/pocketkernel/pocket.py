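"""Geometric model of a binding pocket as a labeled cloud of atoms.

A pocket is an ordered set of atoms, each carrying 3D coordinates (Å) and an
optional scalar label (we use partial charges, in elementary-charge units).
This module provides the basic geometry every similarity measure builds on:
centroid, principal axes, the ellipsoid volume used by the Vol baseline, and
application of rigid motions parameterized by Z-X-Z Euler angles.

Conventions fixed here (and relied upon elsewhere):

* the coordinate covariance is the population (divide-by-N) form;
* semi-axis length of the pocket ellipsoid along principal axis k is
  2·sqrt(eigenvalue_k), a ~2-standard-deviation envelope;
* principal axes are sign-normalized so their largest-magnitude component is
  positive (callers must still treat signs as ambiguous).
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Pocket",
    "RigidMotion",
    "PrincipalFrame",
    "centroid",
    "principal_frame",
    "ellipsoid_volume",
    "apply_motion",
    "euler_to_matrix",
    "euler_from_matrix",
    "read_pocket",
    "write_pocket",
]


@dataclasses.dataclass(frozen=True)
class Pocket:
    """A labeled atom cloud.

    Parameters
    ----------
    coords
        (N, 3) float array of atom positions in Å, N >= 1.
    labels
        Optional (N,) float array of scalar atom labels (partial charges).
    ligand_class
        Optional categorical tag (the ligand the pocket binds).
    id
        Identifier string.
    """

    coords: np.ndarray
    labels: np.ndarray | None = None
    ligand_class: str | None = None
    id: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
            raise ValueError("coords must be a nonempty (N, 3) array")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)
        if self.labels is not None:
            labels = np.asarray(self.labels, dtype=float)
            if labels.shape != (coords.shape[0],):
                raise ValueError("labels must match the number of atoms")
            if not np.all(np.isfinite(labels)):
                raise ValueError("labels must be finite")
            object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def with_coords(self, coords: np.ndarray) -> "Pocket":
        return dataclasses.replace(self, coords=coords)

    def with_labels(self, labels: np.ndarray | None) -> "Pocket":
        return dataclasses.replace(self, labels=labels)


def euler_to_matrix(phi: float, theta: float, psi: float) -> np.ndarray:
    """Rotation matrix for Z-X-Z Euler angles: R = Rz(phi) @ Rx(theta) @ Rz(psi)."""
    cf, sf = math.cos(phi), math.sin(phi)
    ct, st = math.cos(theta), math.sin(theta)
    cp, sp = math.cos(psi), math.sin(psi)
    return np.array(
        [
            [cf * cp - sf * ct * sp, -cf * sp - sf * ct * cp, sf * st],
            [sf * cp + cf * ct * sp, -sf * sp + cf * ct * cp, -cf * st],
            [st * sp, st * cp, ct],
        ]
    )


def euler_from_matrix(R: np.ndarray) -> tuple[float, float, float]:
    """Recover Z-X-Z Euler angles (phi, theta, psi) in [0, 2π) from a rotation.

    At the gimbal configurations theta in {0, π} only phi+psi (resp. phi-psi)
    is determined; psi is set to 0 there.
    """
    R = np.asarray(R, dtype=float)
    ct = float(np.clip(R[2, 2], -1.0, 1.0))
    theta = math.acos(ct)
    if abs(ct) > 1.0 - 1e-12:  # gimbal: only phi ± psi is determined
        phi = math.atan2(R[1, 0], R[0, 0])
        psi = 0.0
    else:
        phi = math.atan2(R[0, 2], -R[1, 2])
        psi = math.atan2(R[2, 0], R[2, 1])
    twopi = 2.0 * math.pi
    return (phi % twopi, theta % twopi, psi % twopi)


@dataclasses.dataclass(frozen=True)
class RigidMotion:
    """A proper rigid motion x -> R x + t with R in Z-X-Z Euler angles."""

    phi: float = 0.0
    theta: float = 0.0
    psi: float = 0.0
    translation: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros(3)
    )

    def __post_init__(self) -> None:
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(t)):
            raise ValueError("translation must be finite")
        object.__setattr__(self, "translation", t)
        for name in ("phi", "theta", "psi"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def rotation(self) -> np.ndarray:
        return euler_to_matrix(self.phi, self.theta, self.psi)

    @classmethod
    def from_matrix(cls, R: np.ndarray, translation: np.ndarray) -> "RigidMotion":
        phi, theta, psi = euler_from_matrix(R)
        return cls(phi, theta, psi, np.asarray(translation, dtype=float))

    def inverse(self) -> "RigidMotion":
        R = self.rotation
        return RigidMotion.from_matrix(R.T, -R.T @ self.translation)

    def compose(self, other: "RigidMotion") -> "RigidMotion":
        """Motion equivalent to applying `other` first, then `self`."""
        R1, R2 = self.rotation, other.rotation
        return RigidMotion.from_matrix(
            R1 @ R2, R1 @ other.translation + self.translation
        )

    def as_vector(self) -> np.ndarray:
        """Pack as (tx, ty, tz, phi, theta, psi)."""
        return np.concatenate([self.translation, [self.phi, self.theta, self.psi]])

    @classmethod
    def from_vector(cls, v: Sequence[float]) -> "RigidMotion":
        v = np.asarray(v, dtype=float)
        return cls(float(v[3]), float(v[4]), float(v[5]), v[:3])


@dataclasses.dataclass(frozen=True)
class PrincipalFrame:
    """Centroid plus principal axes of a pocket, ordered by descending spread.

    ``axes`` is a 3×3 array whose *columns* are the orthonormal principal
    directions; ``semi_axis_lengths`` are the 2·sqrt(eigenvalue) ellipsoid
    semi-axes in Å, sorted descending.
    """

    center: np.ndarray
    axes: np.ndarray
    semi_axis_lengths: np.ndarray


def centroid(p: Pocket) -> np.ndarray:
    """Geometric center (arithmetic mean) of the pocket atoms."""
    if p.n_atoms == 0:
        raise ValueError("empty pocket")
    return p.coords.mean(axis=0)


def principal_frame(p: Pocket) -> PrincipalFrame:
    """Principal axes of the atom cloud about its centroid.

    Eigenvectors of the population covariance, ordered by descending
    eigenvalue and sign-normalized (largest-magnitude component positive).
    Raises on a degenerate (all atoms coincident) cloud.
    """
    c = centroid(p)
    X = p.coords - c
    if p.n_atoms < 2 or np.max(np.abs(X)) < 1e-12:
        raise ValueError("degenerate cloud: all atoms coincident")
    cov = (X.T @ X) / p.n_atoms
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for k in range(3):
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]
    if np.linalg.det(evecs) < 0:  # keep a right-handed frame
        evecs[:, 2] = -evecs[:, 2]
    return PrincipalFrame(center=c, axes=evecs, semi_axis_lengths=2.0 * np.sqrt(evals))


def ellipsoid_volume(p: Pocket) -> float:
    """Volume (Å³) of the pocket's principal-axis ellipsoid, (4/3)π·a·b·c."""
    a, b, c = principal_frame(p).semi_axis_lengths
    return (4.0 / 3.0) * math.pi * a * b * c


def apply_motion(p: Pocket, m: RigidMotion) -> Pocket:
    """Apply the rigid motion to every atom; labels and order are preserved."""
    R = m.rotation
    return p.with_coords(p.coords @ R.T + m.translation)


# ---------------------------------------------------------------------------
# Pocket text format: one atom per line, `x y z [charge]`, '#' comments.
# ---------------------------------------------------------------------------

def write_pocket(p: Pocket, path: str | Path) -> None:
    """Write a pocket in the text format (6-decimal coordinates)."""
    path = Path(path)
    lines = [f"# pocket {p.id}"]
    if p.ligand_class is not None:
        lines.append(f"# ligand_class {p.ligand_class}")
    for i in range(p.n_atoms):
        x, y, z = p.coords[i]
        row = f"{x:.6f} {y:.6f} {z:.6f}"
        if p.labels is not None:
            row += f" {p.labels[i]:.6f}"
        lines.append(row)
    path.write_text("\n".join(lines) + "\n")


def read_pocket(path: str | Path) -> Pocket:
    """Read a pocket from the text format written by :func:`write_pocket`."""
    path = Path(path)
    coords: list[list[float]] = []
    labels: list[float] = []
    pid = path.stem
    ligand_class = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            fields = line[1:].split()
            if len(fields) == 2 and fields[0] == "pocket":
                pid = fields[1]
            elif len(fields) == 2 and fields[0] == "ligand_class":
                ligand_class = fields[1]
            continue
        parts = line.split()
        if len(parts) not in (3, 4):
            raise ValueError(f"{path}:{lineno}: expected 'x y z [charge]'")
        coords.append([float(v) for v in parts[:3]])
        if len(parts) == 4:
            labels.append(float(parts[3]))
    if not coords:
        raise ValueError(f"{path}: no atoms")
    if labels and len(labels) != len(coords):
        raise ValueError(f"{path}: mixed labeled and unlabeled atoms")
    return Pocket(
        coords=np.array(coords),
        labels=np.array(labels) if labels else None,
        ligand_class=ligand_class,
        id=pid,
    )
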