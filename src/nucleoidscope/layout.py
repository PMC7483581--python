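"""Genome layout: chromosomes, replication landmarks, and annotated regions.

A :class:`GenomeLayout` records everything the rest of the package needs to
know about the genome being analysed: an ordered set of (usually circular)
chromosomes, the replication origin (*ori*) and terminus (*ter*) of each, the
position of the chromosome-2 replication-licensing site *crtS* on the first
chromosome, and any prophage regions.  The default layout emulates a
two-chromosome *Vibrio*-like genome of ~5.2 Mb (3.2 Mb + 2.0 Mb).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome sizes and landmark coordinates.

    Parameters
    ----------
    chroms
        Ordered tuple of ``(name, length_bp, circular)``.
    ori, ter
        Per-chromosome replication origin / terminus positions (bp,
        0-based).
    crts
        ``(chrom, position_bp, length_bp)`` of the crtS site, or ``None``.
    prophage_regions
        Tuple of ``(chrom, start_bp, end_bp)`` half-open intervals.
    """

    chroms: tuple[tuple[str, int, bool], ...]
    ori: dict[str, int] = field(default_factory=dict)
    ter: dict[str, int] = field(default_factory=dict)
    crts: tuple[str, int, int] | None = None
    prophage_regions: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.chroms:
            raise ValueError("layout needs at least one chromosome")
        lengths = self.lengths
        for name, length, _ in self.chroms:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        for label, posmap in (("ori", self.ori), ("ter", self.ter)):
            for name, pos in posmap.items():
                if name not in lengths:
                    raise ValueError(f"{label} given for unknown chromosome {name!r}")
                if not 0 <= pos < lengths[name]:
                    raise ValueError(f"{label} of {name!r} outside [0, length)")
        for name in self.ori:
            if name in self.ter and self.ori[name] == self.ter[name]:
                raise ValueError(f"ori == ter on chromosome {name!r}")
        if self.crts is not None:
            chrom, pos, m = self.crts
            if chrom != self.chroms[0][0]:
                raise ValueError("crtS must lie on the first chromosome")
            if not 0 <= pos < lengths[chrom]:
                raise ValueError("crtS position outside chromosome")
            if m <= 0:
                raise ValueError("crtS length must be positive")
        seen: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.prophage_regions:
            if chrom not in lengths:
                raise ValueError(f"prophage region on unknown chromosome {chrom!r}")
            if not (0 <= start < end <= lengths[chrom]):
                raise ValueError("prophage region must satisfy 0 <= start < end <= length")
            for s, e in seen.setdefault(chrom, []):
                if start < e and s < end:
                    raise ValueError("prophage regions must not overlap")
            seen[chrom].append((start, end))

    @property
    def names(self) -> list[str]:
        return [c[0] for c in self.chroms]

    @property
    def lengths(self) -> dict[str, int]:
        return {c[0]: c[1] for c in self.chroms}

    def length(self, chrom: str) -> int:
        return self.lengths[chrom]

    def is_circular(self, chrom: str) -> bool:
        for name, _, circ in self.chroms:
            if name == chrom:
                return circ
        raise KeyError(chrom)

    @property
    def total_length(self) -> int:
        return sum(c[1] for c in self.chroms)

    def circular_distance(self, chrom: str, a: int, b: int) -> int:
        """Shortest arc (bp) between two positions on a chromosome."""
        L = self.length(chrom)
        d = abs(a - b)
        if self.is_circular(chrom):
            d = min(d, L - d)
        return d


def make_genome_layout(
    chrom_lengths: dict[str, int] | None = None,
    *,
    circular: bool = True,
    ori: dict[str, int] | None = None,
    ter: dict[str, int] | None = None,
    crts_rel: float | None = 0.4,
    crts_length: int = 150,
    crts_chrom: str | None = None,
    prophage_regions: tuple[tuple[str, int, int], ...] | list | None = None,
) -> GenomeLayout:
    """Build a :class:`GenomeLayout`, placing crtS along the first replichore.

    The crtS site is placed at ``ori1 + r * replichore_length`` where the
    replichore runs from *ori* to *ter* of the first chromosome in the
    direction of increasing coordinate (wrapping on circular chromosomes)
    and ``r = crts_rel``.  ``r = 0.4`` mirrors a site two fifths of the way
    from *ori1* to *ter1*; pass ``crts_rel=None`` for no crtS.
    """
    if chrom_lengths is None:
        chrom_lengths = {"chr1": 3_200_000, "chr2": 2_000_000}
    names = list(chrom_lengths)
    if ori is None:
        ori = {name: 0 for name in names}
    if ter is None:
        ter = {
            name: (ori.get(name, 0) + chrom_lengths[name] // 2) % chrom_lengths[name]
            for name in names
        }
    crts = None
    if crts_rel is not None:
        first = names[0]
        if crts_chrom is not None and crts_chrom != first:
            raise ValueError("crtS must lie on the first chromosome")
        if not 0.0 <= crts_rel < 1.0 + 1e-12:
            raise ValueError("crts_rel must lie in [0, 1]")
        L1 = chrom_lengths[first]
        arm = (ter[first] - ori[first]) % L1
        if arm == 0:
            raise ValueError("ori == ter on the first chromosome")
        pos = int(round(ori[first] + crts_rel * arm)) % L1
        crts = (first, pos, crts_length)
    if prophage_regions is None:
        prophage_regions = ()
    return GenomeLayout(
        chroms=tuple((name, chrom_lengths[name], circular) for name in names),
        ori=dict(ori),
        ter=dict(ter),
        crts=crts,
        prophage_regions=tuple(tuple(r) for r in prophage_regions),
    )


def default_layout() -> GenomeLayout:
    """Two circular chromosomes totalling 5.2 Mb with a planted prophage.

    chr1 is 3.2 Mb with ori1 at 0, ter1 at 1.6 Mb and crtS two fifths of
    the way along the ori1->ter1 replichore; chr2 is 2.0 Mb.  A single
    200 kb prophage interval sits on chr1 downstream of crtS.
    """
    return make_genome_layout(
        {"chr1": 3_200_000, "chr2": 2_000_000},
        prophage_regions=(("chr1", 1_300_000, 1_500_000),),
    )
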