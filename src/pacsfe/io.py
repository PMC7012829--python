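"""File formats, configuration loading, and run manifests.

PDB (fixed-column ATOM/HETATM, MODEL/ENDMDL for frames) is handled through
biotite; coordinates are Å, times ps, energies unit-tagged in table
headers.  Only orthorhombic boxes are supported.  Residue ids are preserved
as-is from input (no renumbering).
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .structure import Structure, Trajectory


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------


def _to_atom_array(structure: Structure):
    import biotite.structure as bst

    n = structure.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = structure.coords.astype(np.float32)
    arr.chain_id = structure.chains
    arr.res_id = structure.resids
    arr.res_name = structure.resnames
    arr.atom_name = structure.names
    arr.element = structure.elements
    arr.hetero = structure.mask(water=True)
    if structure.box is not None:
        arr.box = np.diag(structure.box).astype(np.float32)
    return arr


def _box_from_biotite(box: np.ndarray | None) -> np.ndarray | None:
    if box is None:
        return None
    box = np.asarray(box, dtype=float)
    if box.ndim == 3:  # stack: one box per frame; use the first
        box = box[0]
    off_diag = box - np.diag(np.diag(box))
    if np.any(np.abs(off_diag) > 1e-3):
        raise ParseError("only orthorhombic boxes are supported")
    diag = np.diag(box)
    if np.all(diag > 0):
        return diag
    return None


def _from_atom_array(arr, box) -> Structure:
    return Structure(
        names=np.asarray(arr.atom_name),
        elements=np.asarray(arr.element),
        resnames=np.asarray(arr.res_name),
        resids=np.asarray(arr.res_id),
        chains=np.asarray(arr.chain_id),
        coords=np.asarray(arr.coord, dtype=float),
        box=box,
    )


def read_pdb(path: str | Path) -> Structure | Trajectory:
    """Read a PDB file; a multi-model file becomes a :class:`Trajectory`."""
    import biotite.structure.io.pdb as pdb

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        f = pdb.PDBFile.read(str(path))
        stack = f.get_structure()  # AtomArrayStack
    except Exception as exc:  # biotite reports the offending line
        raise ParseError(f"failed to parse {path}: {exc}") from exc
    box = _box_from_biotite(stack.box)
    n_models = stack.stack_depth()
    if n_models == 1:
        return _from_atom_array(stack[0], box)
    topology = _from_atom_array(stack[0], box)
    return Trajectory(
        topology=topology,
        coords=np.asarray(stack.coord, dtype=float),
        boxes=None if box is None else np.tile(box, (n_models, 1)),
    )


def write_pdb(path: str | Path, obj: Structure | Trajectory) -> None:
    import biotite.structure as bst
    import biotite.structure.io.pdb as pdb

    if isinstance(obj, Trajectory):
        arrays = [_to_atom_array(obj[i]) for i in range(obj.n_frames)]
        stack = bst.stack(arrays)
        f = pdb.PDBFile()
        f.set_structure(stack)
    else:
        f = pdb.PDBFile()
        f.set_structure(_to_atom_array(obj))
    f.write(str(Path(path)))


# ---------------------------------------------------------------------------
# Tables and config
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path, float_format: str = "%.6g") -> None:
    """Schema-stable CSV output at fixed float precision."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=float_format)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(x: Any):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def load_config(path: str | Path) -> dict:
    """Load a structured-text config (JSON or YAML, by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every pipeline output: config
    echo, seeds, package version, stage timings, and output digests.
    Deterministic stages rerun with the same config and seeds reproduce the
    same digests."""

    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    version: str = ""
    timings: dict = field(default_factory=dict)
    digests: dict = field(default_factory=dict)

    def add_outputs(self, out_dir: str | Path, patterns: tuple[str, ...] = ("*.csv", "*.json", "*.pdb")) -> None:
        out = Path(out_dir)
        for pat in patterns:
            for p in sorted(out.glob(pat)):
                if p.name == "manifest.json":
                    continue
                self.digests[p.name] = file_digest(p)

    def write(self, out_dir: str | Path) -> None:
        from . import __version__

        self.version = self.version or __version__
        write_json(
            {
                "config": self.config,
                "seeds": self.seeds,
                "version": self.version,
                "timings": self.timings,
                "digests": self.digests,
            },
            Path(out_dir) / "manifest.json",
        )
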