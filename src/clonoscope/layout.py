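"""Lineage-barcode layout: fixed anchors bridging random stretches.

A lineage barcode is a short synthetic oligonucleotide (37 bp by default)
in which runs of random bases are separated by fixed "bridge" bases.  The
fixed bases let degenerate synthesis be verified and give extraction a
template; the random positions carry the clonal identity.  The exact
fixed/random arrangement differs between library builds, so it is
configuration rather than a constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_DNA = frozenset("ACGT")


@dataclass(frozen=True)
class BarcodeLayout:
    """Ordered fixed/random segments of a lineage barcode.

    Parameters
    ----------
    segments
        Sequence of ``("fixed", bases)`` or ``("random", length)`` tuples,
        5' to 3'.  Fixed segments give their literal bases; random segments
        give the number of degenerate (N) positions.
    """

    segments: tuple[tuple[str, object], ...]

    def __post_init__(self) -> None:
        for kind, payload in self.segments:
            if kind == "fixed":
                if not payload or set(payload) - _DNA:
                    raise ValueError(f"fixed segment must be non-empty A/C/G/T, got {payload!r}")
            elif kind == "random":
                if not isinstance(payload, int) or payload <= 0:
                    raise ValueError(f"random segment length must be a positive int, got {payload!r}")
            else:
                raise ValueError(f"unknown segment kind {kind!r}")

    @property
    def length(self) -> int:
        return sum(len(p) if k == "fixed" else p for k, p in self.segments)

    @property
    def random_positions(self) -> tuple[int, ...]:
        """0-based offsets of the degenerate positions within the barcode."""
        out: list[int] = []
        pos = 0
        for kind, payload in self.segments:
            if kind == "fixed":
                pos += len(payload)
            else:
                out.extend(range(pos, pos + payload))
                pos += payload
        return tuple(out)

    @property
    def fixed_template(self) -> str:
        """Barcode template with N at the random positions."""
        parts = []
        for kind, payload in self.segments:
            parts.append(payload if kind == "fixed" else "N" * payload)
        return "".join(parts)

    def matches_fixed(self, barcode: str) -> bool:
        """True when ``barcode`` agrees with every fixed position."""
        if len(barcode) != self.length:
            return False
        return all(t == "N" or t == b for t, b in zip(self.fixed_template, barcode))

    def render(self, random_bases: str) -> str:
        """Fill the random positions with ``random_bases`` (5'→3' order)."""
        if len(random_bases) != len(self.random_positions):
            raise ValueError(
                f"need {len(self.random_positions)} random bases, got {len(random_bases)}"
            )
        seq = list(self.fixed_template)
        for base, pos in zip(random_bases, self.random_positions):
            seq[pos] = base
        return "".join(seq)


#: 37-bp default: three 4-bp fixed anchors bridging three random stretches
#: (8 + 9 + 8 = 25 degenerate positions).
DEFAULT_LAYOUT = BarcodeLayout(
    segments=(
        ("random", 8),
        ("fixed", "TGCA"),
        ("random", 9),
        ("fixed", "GATC"),
        ("random", 8),
        ("fixed", "CTAG"),
    )
)


@dataclass(frozen=True)
class ReadStructure:
    """Where the lineage barcode sits inside a sequencing read.

    Reads carry ``...5' anchor | barcode | 3' anchor...``; the anchors are
    vector-derived constant sequence flanking the barcode cassette and are
    distinct from the fixed bridges *inside* the barcode.
    """

    anchor5: str = "ACGTACGTAC"
    anchor3: str = "TTGCAGGTCA"
    barcode_length: int = 37
    #: how far into the read the 5' anchor may start
    max_anchor_offset: int = 10
    layout: BarcodeLayout = field(default=DEFAULT_LAYOUT)

    def __post_init__(self) -> None:
        if self.layout.length != self.barcode_length:
            raise ValueError(
                f"layout length {self.layout.length} != barcode_length {self.barcode_length}"
            )

    @property
    def min_read_length(self) -> int:
        return len(self.anchor5) + self.barcode_length + len(self.anchor3)
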