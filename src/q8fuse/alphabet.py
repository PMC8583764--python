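"""Class and residue alphabets shared across the package.

Secondary structure is predicted in the eight DSSP states:
B (isolated beta bridge), E (extended strand), G (3-10 helix),
H (alpha helix), I (pi helix), L (loop/irregular), S (bend) and
T (hydrogen-bonded turn).  The ordering of the eight symbols fixes
the column order of every probability matrix and weight matrix in a
run; it is configurable but must stay constant within a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Default eight-state ordering (alphabetical).
DSSP8 = ("B", "E", "G", "H", "I", "L", "S", "T")

#: The 20 standard amino-acid letters plus the wildcard "X", in the
#: default column order of the one-hot block.
AA_LETTERS = "ACDEFGHIKLMNPQRSTVWYX"


@dataclass(frozen=True)
class ClassAlphabet:
    """Ordered alphabet of the eight secondary-structure states.

    Maps structure symbols to 0-based column indices and back.  Exactly
    eight distinct symbols are required.
    """

    labels: tuple[str, ...] = DSSP8
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        if len(labels) != 8:
            raise ValueError(f"expected exactly 8 class symbols, got {len(labels)}")
        if len(set(labels)) != 8:
            raise ValueError(f"class symbols must be distinct: {labels!r}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(labels)})

    def index_of(self, symbol: str) -> int:
        try:
            return self._index[symbol]
        except KeyError:
            raise KeyError(f"unknown class symbol {symbol!r}; alphabet is {self.labels!r}") from None

    def symbol(self, index: int) -> str:
        return self.labels[index]

    def __len__(self) -> int:
        return 8

    def __iter__(self):
        return iter(self.labels)


#: Shared default instance.
DEFAULT_ALPHABET = ClassAlphabet()
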