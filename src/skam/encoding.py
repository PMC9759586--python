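"""Relational structures, cueing structures and sequence structures.

A relational structure is a set of ``L`` (object, attribute) pairs drawn from
item dictionaries; its distributed representation is the sum of the ``L``
binding vectors and is therefore permutation invariant.  A cueing structure
sums a subset of ``L0 <= L`` pairs and serves as the retrieval cue for the
attractor network.  Temporal sequences are represented as chains of
asymmetric bindings between consecutive events.

Items are row vectors with i.i.d. Normal(0, 1/N) components, so an encoded
structure has component variance growing like L/N and its binarized form is
an unbiased +-1 pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .vsa import BindingScheme, bind, hard_sign

__all__ = [
    "Dictionary",
    "EncodedStructure",
    "RelationalStructure",
    "SequenceStructure",
    "binarize",
    "encode_cue",
    "encode_sequence",
    "encode_structure",
]


@dataclass
class Dictionary:
    """A store of ``D`` item vectors (rows), used for encoding and clean-up."""

    items: np.ndarray
    role: str = "object"

    def __post_init__(self) -> None:
        self.items = np.asarray(self.items, dtype=float)
        if self.items.ndim != 2:
            raise ValueError("dictionary items must form a (D, N) matrix")
        if self.items.shape[0] < 1:
            raise ValueError("dictionary must contain at least one item")

    @property
    def n_items(self) -> int:
        return self.items.shape[0]

    @property
    def n_units(self) -> int:
        return self.items.shape[1]

    def __len__(self) -> int:
        return self.n_items

    def __getitem__(self, idx) -> np.ndarray:
        return self.items[idx]


@dataclass(frozen=True)
class RelationalStructure:
    """An unordered set of (object_index, attribute_index) pairs."""

    pairs: tuple[tuple[int, int], ...]

    def __init__(self, pairs: Sequence[Sequence[int]]):
        pairs = tuple((int(o), int(a)) for o, a in pairs)
        if len(pairs) < 1:
            raise ValueError("a structure needs at least one pair")
        object.__setattr__(self, "pairs", pairs)

    @property
    def L(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class SequenceStructure:
    """An ordered list of object indices; encodes to L-1 bound pairs."""

    item_indices: tuple[int, ...]

    def __init__(self, item_indices: Sequence[int]):
        idx = tuple(int(i) for i in item_indices)
        if len(idx) < 2:
            raise ValueError("a sequence needs at least two items")
        object.__setattr__(self, "item_indices", idx)

    @property
    def L(self) -> int:
        return len(self.item_indices)


@dataclass
class EncodedStructure:
    """A structure's N-vector representation plus provenance."""

    values: np.ndarray
    source: RelationalStructure | SequenceStructure | None = None
    cue_positions: tuple[int, ...] | None = field(default=None)

    @property
    def n_units(self) -> int:
        return self.values.shape[0]


def _check_indices(structure: RelationalStructure, objects: Dictionary, attributes: Dictionary) -> None:
    for o, a in structure.pairs:
        if not (0 <= o < objects.n_items):
            raise IndexError(f"object index {o} outside dictionary of size {objects.n_items}")
        if not (0 <= a < attributes.n_items):
            raise IndexError(f"attribute index {a} outside dictionary of size {attributes.n_items}")


def encode_structure(
    structure: RelationalStructure,
    objects: Dictionary,
    attributes: Dictionary,
    scheme: BindingScheme | None = None,
) -> EncodedStructure:
    """Sum the ``L`` pair bindings into one N-vector.

    The pairs are summed in canonical (sorted) order so that any reordering
    of ``structure.pairs`` produces a bit-identical vector.
    """
    scheme = scheme or BindingScheme.symmetric()
    _check_indices(structure, objects, attributes)
    values = np.zeros(objects.n_units)
    for o, a in sorted(structure.pairs):
        values += bind(objects[o], attributes[a], scheme)
    return EncodedStructure(values=values, source=structure)


def encode_cue(
    structure: RelationalStructure,
    objects: Dictionary,
    attributes: Dictionary,
    cue_size: int | None = None,
    cue_positions: Sequence[int] | None = None,
    scheme: BindingScheme | None = None,
) -> EncodedStructure:
    """Encode a cueing structure from a subset of the pairs.

    By default the cue is the prefix of ``cue_size`` pairs; an explicit list
    of pair positions may be given instead (e.g. a random subset).  The
    positions are recorded on the result so that decode queries can be drawn
    from pairs outside the cue.
    """
    if cue_positions is None:
        if cue_size is None:
            raise ValueError("provide either cue_size or cue_positions")
        positions = tuple(range(cue_size))
    else:
        positions = tuple(int(p) for p in cue_positions)
        if cue_size is not None and cue_size != len(positions):
            raise ValueError("cue_size disagrees with cue_positions")
    if len(positions) < 1 or len(positions) > structure.L:
        raise ValueError(f"cue size must be in [1, L={structure.L}]")
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate cue positions")
    if any(p < 0 or p >= structure.L for p in positions):
        raise ValueError("cue positions outside the structure")

    scheme = scheme or BindingScheme.symmetric()
    _check_indices(structure, objects, attributes)
    values = np.zeros(objects.n_units)
    for p in positions:
        o, a = structure.pairs[p]
        values += bind(objects[o], attributes[a], scheme)
    return EncodedStructure(values=values, source=structure, cue_positions=positions)


def encode_sequence(
    sequence: SequenceStructure,
    items: Dictionary,
    scheme: BindingScheme | None = None,
    include_first_item: bool = False,
) -> EncodedStructure:
    """Encode an ordered sequence as the sum of L-1 consecutive bindings.

    Requires an asymmetric scheme so that the chain can be unrolled forward
    by querying with the preceding event.  ``include_first_item`` adds the
    first item itself to the representation, making it usable as a retrieval
    cue on its own.
    """
    scheme = scheme or BindingScheme.asymmetric()
    if scheme.mode != "hrr_asymmetric":
        raise ValueError("sequence encoding requires the asymmetric binding scheme")
    idx = sequence.item_indices
    for i in idx:
        if not (0 <= i < items.n_items):
            raise IndexError(f"item index {i} outside dictionary of size {items.n_items}")
    values = np.zeros(items.n_units)
    for earlier, later in zip(idx[:-1], idx[1:]):
        values += bind(items[earlier], items[later], scheme)
    if include_first_item:
        values += items[idx[0]]
    return EncodedStructure(values=values, source=sequence)


def binarize(encoded: EncodedStructure | np.ndarray) -> np.ndarray:
    """Element-wise sign of the representation; exact zeros map to +1."""
    values = encoded.values if isinstance(encoded, EncodedStructure) else np.asarray(encoded)
    return hard_sign(values)
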