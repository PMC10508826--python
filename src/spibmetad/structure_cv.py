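"""Collective variables from kinase structures and DFG-state classification.

The CV basis set is a named list of inter-residue atom-pair distances (Å),
defined by a :class:`CVSchema`.  Two entries are special: the Dunbrack
distances ``d1`` (salt-bridge Lys Cβ – αC-helix Glu Cβ) and ``d2``
(salt-bridge Lys Cβ – DFG-Asp Cβ), whose thresholds classify the DFG motif
as in (active), out (inactive) or inter (the "DFG-up" transition state).

The classification rule used throughout (distances in Å):

* ``IN``         if d1 < 11 and d2 > 14
* ``OUT``        if d1 > 11 and d2 < 14
* ``INTER``      if d1 < 11 and d2 < 11
* ``UNASSIGNED`` if d1 > 11 and d2 > 14 (the physically unlikely "DFG-down")
* ``GAP``        otherwise — the band d1 < 11, 11 ≤ d2 ≤ 14 and any boundary
  equality, labelled explicitly rather than silently merged into a state.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "CVSchema", "CVEntry", "CVFrame", "DunbrackDistances", "DunbrackState",
    "SchemaUnresolvableError", "DunbrackEntriesMissingError", "ConstantCVError",
    "DUNBRACK_D1", "DUNBRACK_D2", "load_pdb_models",
    "extract_cvs", "dunbrack_distances", "classify_dfg",
    "filter_unphysical", "standardize", "destandardize",
]

logger = logging.getLogger(__name__)

#: Canonical schema names for the two Dunbrack classification distances.
DUNBRACK_D1 = "d1"
DUNBRACK_D2 = "d2"

#: Å thresholds of the Dunbrack distance rule.
DFG_THRESHOLDS = (11.0, 14.0)

#: Allowed consecutive Cα–Cα distance window (Å); brackets the 3.8 Å trans
#: spacing.  Anything outside is treated as a broken backbone.
CA_CA_WINDOW = (2.5, 4.5)


class SchemaUnresolvableError(KeyError):
    """A schema (residue, atom) pair could not be found in the structure."""


class DunbrackEntriesMissingError(KeyError):
    """Schema lacks the mandatory ``d1``/``d2`` Dunbrack entries."""


class ConstantCVError(ValueError):
    """A CV column has zero variance and cannot be standardized."""


@dataclass(frozen=True)
class CVEntry:
    name: str
    residue_a: int
    atom_a: str
    residue_b: int
    atom_b: str

    def __post_init__(self) -> None:
        if self.residue_a < 1 or self.residue_b < 1:
            raise ValueError(f"{self.name}: residue ids are 1-based, got "
                             f"{self.residue_a}, {self.residue_b}")


@dataclass
class CVSchema:
    """Ordered, named list of inter-residue atom-pair distances (Å).

    The order is fixed for a run: every :class:`CVFrame` produced under a
    schema carries its values in schema order.
    """

    entries: list[CVEntry]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate CV names in schema: {names}")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CVSchema":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(entries=[CVEntry(**e) for e in raw["cvs"]])

    def to_yaml(self, path: str | Path) -> None:
        raw = {"cvs": [vars(e) for e in self.entries]}
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


@dataclass
class CVFrame:
    """One structure's CV values, in schema order, in Å."""

    values: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError(f"{self.source_id or 'frame'}: CV values must be "
                             "finite and > 0")


@dataclass(frozen=True)
class DunbrackDistances:
    d1: float
    d2: float

    def __post_init__(self) -> None:
        if not (self.d1 > 0 and self.d2 > 0):
            raise ValueError(f"Dunbrack distances must be positive: {self}")


class DunbrackState(enum.Enum):
    IN = "IN"
    OUT = "OUT"
    INTER = "INTER"
    UNASSIGNED = "UNASSIGNED"
    GAP = "GAP"


def load_pdb_models(path: str | Path):
    """Load all models of a PDB file as a list of biotite ``AtomArray``."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()
    return [stack[i] for i in range(stack.stack_depth())]


def _resolve_atom(structure, res_id: int, atom_name: str, entry_name: str) -> np.ndarray:
    mask = (structure.res_id == res_id) & (structure.atom_name == atom_name)
    if not mask.any() and atom_name == "CB":
        # glycine carries no Cβ; Cα is the standard stand-in
        gly = (structure.res_id == res_id) & (structure.res_name == "GLY")
        if gly.any():
            logger.info("CV %s: residue %d is glycine, using CA for CB",
                        entry_name, res_id)
            mask = gly & (structure.atom_name == "CA")
    if not mask.any():
        raise SchemaUnresolvableError(
            f"schema-unresolvable: entry {entry_name!r} needs atom "
            f"{atom_name} of residue {res_id}, absent from structure")
    return np.asarray(structure.coord[mask][0], dtype=float)


def extract_cvs(structure, schema: CVSchema, source_id: str = "") -> CVFrame:
    """Compute the schema's inter-atomic distances (Å) for one structure.

    ``structure`` is a biotite ``AtomArray`` (one model).  Cβ requests on
    glycine fall back to Cα.  A zero distance (atom paired with itself)
    violates the CVFrame invariant and raises.
    """
    values = np.empty(len(schema))
    for i, e in enumerate(schema.entries):
        a = _resolve_atom(structure, e.residue_a, e.atom_a, e.name)
        b = _resolve_atom(structure, e.residue_b, e.atom_b, e.name)
        values[i] = float(np.linalg.norm(a - b))
    return CVFrame(values=values, source_id=source_id)


def dunbrack_distances(frame: CVFrame, schema: CVSchema) -> DunbrackDistances:
    """Pull the named Dunbrack distances out of a CV frame."""
    names = schema.names
    try:
        i1, i2 = names.index(DUNBRACK_D1), names.index(DUNBRACK_D2)
    except ValueError as exc:
        raise DunbrackEntriesMissingError(
            f"dunbrack-entries-missing: schema must name entries "
            f"{DUNBRACK_D1!r} and {DUNBRACK_D2!r}, has {names}") from exc
    return DunbrackDistances(d1=float(frame.values[i1]), d2=float(frame.values[i2]))


def classify_dfg(d: DunbrackDistances,
                 thresholds: tuple[float, float] = DFG_THRESHOLDS) -> DunbrackState:
    """Classify the DFG motif from the two Dunbrack distances (Å).

    Total over the (d1, d2) plane: the four open quadrant rules are disjoint
    and everything else — the d1 < t1, t1 ≤ d2 ≤ t2 band and exact boundary
    values — is labelled ``GAP``.
    """
    t1, t2 = thresholds
    d1, d2 = d.d1, d.d2
    if d1 < t1 and d2 > t2:
        return DunbrackState.IN
    if d1 > t1 and d2 < t2:
        return DunbrackState.OUT
    if d1 < t1 and d2 < t1:
        return DunbrackState.INTER
    if d1 > t1 and d2 > t2:
        return DunbrackState.UNASSIGNED
    return DunbrackState.GAP


def classify_dfg_array(d1: np.ndarray, d2: np.ndarray,
                       thresholds: tuple[float, float] = DFG_THRESHOLDS) -> np.ndarray:
    """Vectorized :func:`classify_dfg`; returns an object array of states."""
    d1 = np.asarray(d1, float)
    d2 = np.asarray(d2, float)
    t1, t2 = thresholds
    out = np.full(d1.shape, DunbrackState.GAP, dtype=object)
    out[(d1 < t1) & (d2 > t2)] = DunbrackState.IN
    out[(d1 > t1) & (d2 < t2)] = DunbrackState.OUT
    out[(d1 < t1) & (d2 < t1)] = DunbrackState.INTER
    out[(d1 > t1) & (d2 > t2)] = DunbrackState.UNASSIGNED
    return out


def filter_unphysical(ca_traces: list[np.ndarray],
                      frame_ids: list[str] | None = None,
                      window: tuple[float, float] = CA_CA_WINDOW,
                      ) -> tuple[list[int], list[dict]]:
    """Reject structures with broken backbones.

    A structure is rejected iff any consecutive Cα–Cα distance falls outside
    ``window`` (Å).  Returns the retained indices and a rejection log, one
    dict per rejected structure with the offending bond index and distance.
    """
    if not ca_traces:
        warnings.warn("filter_unphysical: empty input", stacklevel=2)
        return [], []
    if frame_ids is None:
        frame_ids = [str(i) for i in range(len(ca_traces))]
    lo, hi = window
    retained: list[int] = []
    log: list[dict] = []
    for i, trace in enumerate(ca_traces):
        trace = np.asarray(trace, float)
        gaps = np.linalg.norm(np.diff(trace, axis=0), axis=1)
        bad = np.where((gaps < lo) | (gaps > hi))[0]
        if bad.size:
            j = int(bad[0])
            log.append({"index": i, "frame_id": frame_ids[i],
                        "reason": f"broken bond at {j}",
                        "distance": float(gaps[j])})
        else:
            retained.append(i)
    return retained, log


def standardize(frames: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score a CV matrix column-wise with the population (1/N) sd.

    Returns ``(standardized, mean, sd)``; the transform parameters are kept
    so the same scaling can be reapplied to other sequences (mutants) and
    inverted exactly.
    """
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    if frames.shape[0] < 2:
        raise ValueError("standardize needs at least 2 frames")
    mean = frames.mean(axis=0)
    sd = frames.std(axis=0)  # population sd
    zero = np.where(sd == 0)[0]
    if zero.size:
        raise ConstantCVError(f"constant-cv: zero-variance column(s) {zero.tolist()}")
    return (frames - mean) / sd, mean, sd


def destandardize(z: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return np.asarray(z, float) * sd + mean
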