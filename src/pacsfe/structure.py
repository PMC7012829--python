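"""Lightweight molecular containers used by the geometric analyses.

A :class:`Structure` is a flat array-of-atoms record (name, element, residue,
chain, coordinates in Å, optional orthorhombic box); a :class:`Trajectory` is
a frame sequence sharing one topology.  PDB conversion lives in
:mod:`pacsfe.io`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

#: Residue names recognized as water.
WATER_RESNAMES = frozenset({"HOH", "WAT", "SOL", "TIP3", "TIP3P"})


class SelectionError(ValueError):
    """An atom selection matched nothing or referenced missing atoms."""


@dataclass
class Structure:
    names: np.ndarray
    elements: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    chains: np.ndarray
    coords: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.names = np.asarray(self.names, dtype="U6")
        self.elements = np.asarray(self.elements, dtype="U2")
        self.resnames = np.asarray(self.resnames, dtype="U5")
        self.resids = np.asarray(self.resids, dtype=np.int64)
        self.chains = np.asarray(self.chains, dtype="U2")
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=np.float64).reshape(3)
            if not np.all(self.box > 0):
                raise ValueError("box lengths must be positive")
        n = len(self.coords)
        for arr, label in (
            (self.names, "names"),
            (self.elements, "elements"),
            (self.resnames, "resnames"),
            (self.resids, "resids"),
            (self.chains, "chains"),
        ):
            if len(arr) != n:
                raise ValueError(f"{label} has length {len(arr)}, expected {n}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    # -- selections ----------------------------------------------------------

    def mask(
        self,
        chain: str | Sequence[str] | None = None,
        resname: str | Sequence[str] | None = None,
        resid: int | Sequence[int] | None = None,
        name: str | Sequence[str] | None = None,
        element: str | Sequence[str] | None = None,
        water: bool | None = None,
        heavy: bool | None = None,
    ) -> np.ndarray:
        """Boolean mask of atoms matching all given keyword criteria."""

        def _match(values: np.ndarray, wanted) -> np.ndarray:
            if isinstance(wanted, (str, int, np.integer)):
                wanted = [wanted]
            return np.isin(values, np.asarray(list(wanted), dtype=values.dtype))

        m = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            m &= _match(self.chains, chain)
        if resname is not None:
            m &= _match(self.resnames, resname)
        if resid is not None:
            m &= _match(self.resids, resid)
        if name is not None:
            m &= _match(self.names, name)
        if element is not None:
            m &= _match(self.elements, element)
        if water is not None:
            is_w = np.isin(self.resnames, list(WATER_RESNAMES))
            m &= is_w if water else ~is_w
        if heavy is not None:
            is_h = self.elements == "H"
            m &= ~is_h if heavy else is_h
        return m

    def select(self, **criteria) -> np.ndarray:
        """Indices of atoms matching the criteria; error if none match."""
        idx = np.flatnonzero(self.mask(**criteria))
        if idx.size == 0:
            raise SelectionError(f"selection {criteria!r} matched no atoms")
        return idx

    def subset(self, indices: np.ndarray) -> "Structure":
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.flatnonzero(indices)
        return Structure(
            names=self.names[indices],
            elements=self.elements[indices],
            resnames=self.resnames[indices],
            resids=self.resids[indices],
            chains=self.chains[indices],
            coords=self.coords[indices],
            box=None if self.box is None else self.box.copy(),
        )

    def water_oxygen_indices(self) -> np.ndarray:
        """Indices of the per-water counting site (the oxygen atom)."""
        return np.flatnonzero(self.mask(water=True) & (self.elements == "O"))

    def iter_residues(self, indices: np.ndarray | None = None) -> Iterator[tuple[str, int, np.ndarray]]:
        """Yield (chain, resid, atom indices) groups, in first-appearance order."""
        if indices is None:
            indices = np.arange(self.n_atoms)
        seen: dict[tuple[str, int], list[int]] = {}
        for i in indices:
            key = (str(self.chains[i]), int(self.resids[i]))
            seen.setdefault(key, []).append(int(i))
        for (ch, rid), atom_idx in seen.items():
            yield ch, rid, np.asarray(atom_idx)


def concatenate(parts: Sequence[Structure], box: np.ndarray | None = None) -> Structure:
    """Stack structures into one (atoms appended in order)."""
    return Structure(
        names=np.concatenate([p.names for p in parts]),
        elements=np.concatenate([p.elements for p in parts]),
        resnames=np.concatenate([p.resnames for p in parts]),
        resids=np.concatenate([p.resids for p in parts]),
        chains=np.concatenate([p.chains for p in parts]),
        coords=np.concatenate([p.coords for p in parts]),
        box=box,
    )


@dataclass
class Trajectory:
    """Frames sharing one topology.  ``coords`` has shape (n_frames, n_atoms, 3)."""

    topology: Structure
    coords: np.ndarray
    boxes: np.ndarray | None = None
    times: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coords shape {self.coords.shape} does not match topology with "
                f"{self.topology.n_atoms} atoms"
            )
        if self.boxes is not None:
            self.boxes = np.asarray(self.boxes, dtype=np.float64).reshape(-1, 3)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> Structure:
        frame = self.topology.subset(np.arange(self.topology.n_atoms))
        frame.coords = self.coords[i].copy()
        if self.boxes is not None:
            frame.box = self.boxes[i].copy()
        elif self.topology.box is not None:
            frame.box = self.topology.box.copy()
        return frame

    @classmethod
    def from_structures(cls, frames: Sequence[Structure]) -> "Trajectory":
        if not frames:
            raise ValueError("need at least one frame")
        coords = np.stack([f.coords for f in frames])
        boxes = None
        if frames[0].box is not None:
            boxes = np.stack([f.box for f in frames])
        return cls(topology=frames[0], coords=coords, boxes=boxes)


def last_half_window(n_frames: int) -> np.ndarray:
    """Frame indices of the trailing half of a trajectory (the default
    analysis window: equilibrated tail of a simulation)."""
    return np.arange(n_frames // 2, n_frames)
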