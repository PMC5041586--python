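"""Resolve unphased per-locus copy numbers into haplotype pairs.

Gene-content haplotypes of a multi-copy gene cluster are described by a
*signature*: the vector of per-locus copy counts carried on one chromosome.
A sample's genotype vector (total copies per locus) is the element-wise sum
of its two haplotype signatures.  Given a library of known haplotypes with
population frequencies, a genotype is resolved by:

1. rendering the genotype as a concatenated string (*markersig*, e.g. "211")
   and a per-locus regular expression enumerating every per-haplotype value
   compatible with the observed total (e.g. ``(2|1|0)(1|0)(1|0)``);
2. matching the pattern against the library's signature strings to collect
   candidate haplotypes;
3. subtracting each candidate from the genotype (matrix subtraction) and
   keeping pairs whose residual is itself a library haplotype.

Pairs are ranked by combined frequency (the plain product of the two
haplotype frequencies — a ranking score, not a genotype probability: no
Hardy-Weinberg 2pq factor is applied for heterozygous pairs).  Samples with
no valid pair are reported unresolved, with their single-haplotype matches.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)


class HaplotypeError(ValueError):
    """Raised for malformed haplotypes/libraries or marker-order mismatches."""


@dataclass(frozen=True)
class Haplotype:
    """One gene-content haplotype: signature plus population annotation.

    ``cen_motif``/``tel_motif`` label the centromeric and telomeric
    gene-content motifs (e.g. cA01/tB01 in KIR nomenclature).
    """

    haplotype_id: str
    signature: tuple[int, ...]
    count: int = 0
    frequency: float = 0.0
    cen_motif: str = ""
    tel_motif: str = ""

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.signature):
            raise HaplotypeError(f"{self.haplotype_id}: negative signature entry")
        if self.count < 0:
            raise HaplotypeError(f"{self.haplotype_id}: negative count")
        if self.frequency < 0:
            raise HaplotypeError(f"{self.haplotype_id}: negative frequency")


class HaplotypeLibrary:
    """An ordered collection of haplotypes over a fixed marker order."""

    def __init__(self, marker_order: Sequence[str], haplotypes: Iterable[Haplotype] = ()):
        self.marker_order: tuple[str, ...] = tuple(marker_order)
        self.haplotypes: list[Haplotype] = []
        self._by_id: dict[str, Haplotype] = {}
        self._by_signature: dict[tuple[int, ...], list[Haplotype]] = {}
        for h in haplotypes:
            self.add(h)
        total = sum(h.frequency for h in self.haplotypes)
        if self.haplotypes and abs(total - 1.0) > 1e-6:
            logger.warning(
                "library frequencies sum to %.4f, not 1; they are used as-is "
                "(normalised only where sampling requires it)", total
            )

    def add(self, haplotype: Haplotype) -> None:
        if len(haplotype.signature) != len(self.marker_order):
            raise HaplotypeError(
                f"{haplotype.haplotype_id}: signature length {len(haplotype.signature)} "
                f"!= {len(self.marker_order)} markers"
            )
        if haplotype.haplotype_id in self._by_id:
            raise HaplotypeError(f"duplicate haplotype id {haplotype.haplotype_id!r}")
        self.haplotypes.append(haplotype)
        self._by_id[haplotype.haplotype_id] = haplotype
        self._by_signature.setdefault(haplotype.signature, []).append(haplotype)

    def __len__(self) -> int:
        return len(self.haplotypes)

    def __iter__(self):
        return iter(self.haplotypes)

    def __getitem__(self, haplotype_id: str) -> Haplotype:
        return self._by_id[haplotype_id]

    def with_signature(self, signature: Sequence[int]) -> list[Haplotype]:
        return self._by_signature.get(tuple(signature), [])


@dataclass(frozen=True)
class GenotypeVector:
    """A sample's total copy number per library marker, in library order."""

    sample_id: str
    copies: tuple[int, ...]

    @property
    def markersig(self) -> str:
        return markersig(self.copies)


@dataclass(frozen=True)
class HaplotypePair:
    """An unordered pair of library haplotypes summing to a genotype."""

    haplotype_1: Haplotype
    haplotype_2: Haplotype

    @property
    def combined_frequency(self) -> float:
        return self.haplotype_1.frequency * self.haplotype_2.frequency

    @property
    def ids(self) -> tuple[str, str]:
        return (self.haplotype_1.haplotype_id, self.haplotype_2.haplotype_id)


class ResolutionStatus(str, Enum):
    RESOLVED = "RESOLVED"
    UNRESOLVED = "UNRESOLVED"


@dataclass
class Resolution:
    """Outcome of resolving one sample's genotype against a library."""

    sample_id: str
    genotype: tuple[int, ...]
    status: ResolutionStatus
    pairs: list[HaplotypePair] = field(default_factory=list)
    best_pairs: list[HaplotypePair] = field(default_factory=list)
    single_matches: list[Haplotype] = field(default_factory=list)


# ---------------------------------------------------------------------------
# string forms


def markersig(copies: Sequence[int], delimiter: str | None = None) -> str:
    """Concatenate per-marker copy numbers into the genotype string form.

    The undelimited digit form ("211") requires every copy number <= 9;
    pass a delimiter for higher copy numbers.
    """
    copies = _check_copies(copies)
    if delimiter is None:
        if any(c > 9 for c in copies):
            raise ValueError("copy number > 9 requires a delimiter")
        return "".join(str(c) for c in copies)
    return delimiter.join(str(c) for c in copies)


def regex_pattern(copies: Sequence[int], delimiter: str | None = None) -> str:
    """Per-marker alternation of all copy numbers from the observed total down to 0.

    A genotype (2, 1, 1) yields ``(2|1|0)(1|0)(1|0)``: each group enumerates
    the values one haplotype may carry at that locus.
    """
    copies = _check_copies(copies)
    if delimiter is None and any(c > 9 for c in copies):
        raise ValueError("copy number > 9 requires a delimiter")
    groups = ["(" + "|".join(str(v) for v in range(c, -1, -1)) + ")" for c in copies]
    return (re.escape(delimiter) if delimiter else "").join(groups)


def _check_copies(copies: Sequence[int]) -> tuple[int, ...]:
    out = tuple(int(c) for c in copies)
    if any(c < 0 for c in out):
        raise ValueError("negative copy number")
    return out


# ---------------------------------------------------------------------------
# matching and subtraction


def match_library(
    pattern: str | Sequence[int], library: HaplotypeLibrary
) -> list[Haplotype]:
    """All library haplotypes whose signature string matches the genotype pattern.

    ``pattern`` may be a genotype copy vector (the pattern is built with
    :func:`regex_pattern`) or a ready pattern string.  Signatures are
    rendered with the same delimiter convention before matching; matching a
    signature is equivalent to the element-wise test signature <= genotype.
    """
    delim = "-" if any(c > 9 for h in library for c in h.signature) else None
    if not isinstance(pattern, str):
        if len(pattern) != len(library.marker_order):
            raise HaplotypeError(
                f"genotype has {len(pattern)} markers, library has {len(library.marker_order)}"
            )
        pattern = regex_pattern(pattern, delimiter=delim)
    n_groups = pattern.count("(")
    if n_groups != len(library.marker_order):
        raise HaplotypeError(
            f"pattern has {n_groups} marker groups, library has {len(library.marker_order)}"
        )
    compiled = re.compile(pattern)
    return [
        h for h in library
        if compiled.fullmatch(markersig(h.signature, delimiter=delim))
    ]


def complement(
    genotype: Sequence[int], haplotype: Haplotype | Sequence[int]
) -> tuple[int, ...] | None:
    """Element-wise genotype minus haplotype; None if any entry goes negative."""
    sig = haplotype.signature if isinstance(haplotype, Haplotype) else tuple(haplotype)
    if len(sig) != len(genotype):
        raise HaplotypeError("marker-order length mismatch")
    residual = tuple(int(g) - int(h) for g, h in zip(genotype, sig))
    if any(r < 0 for r in residual):
        return None
    return residual


def _pair_sort_key(pair: HaplotypePair):
    return (-pair.combined_frequency, pair.ids)


def enumerate_pairs(
    genotype: Sequence[int], library: HaplotypeLibrary
) -> list[HaplotypePair]:
    """Every unordered library pair (self-pairs included) summing to the genotype.

    Ordered by descending combined frequency, then haplotype ids.
    """
    genotype = _check_copies(genotype)
    candidates = match_library(genotype, library)
    seen: set[tuple[str, str]] = set()
    pairs: list[HaplotypePair] = []
    for h1 in candidates:
        residual = complement(genotype, h1)
        if residual is None:
            continue
        for h2 in library.with_signature(residual):
            a, b = sorted((h1, h2), key=lambda h: h.haplotype_id)
            key = (a.haplotype_id, b.haplotype_id)
            if key in seen:
                continue
            seen.add(key)
            pairs.append(HaplotypePair(a, b))
    pairs.sort(key=_pair_sort_key)
    return pairs


def resolve_sample(
    genotype: Sequence[int],
    library: HaplotypeLibrary,
    sample_id: str = "",
) -> Resolution:
    """Resolve one genotype: all pairs and best pair(s), or single matches.

    Best pairs are all pairs attaining the maximal combined frequency (ties
    are kept).  Unresolved samples list the haplotypes that individually fit
    under the genotype, as candidates for manual follow-up.
    """
    genotype = _check_copies(genotype)
    pairs = enumerate_pairs(genotype, library)
    if pairs:
        top = pairs[0].combined_frequency
        best = [p for p in pairs if p.combined_frequency == top]
        return Resolution(sample_id, genotype, ResolutionStatus.RESOLVED, pairs, best)
    singles = match_library(genotype, library) if len(library) else []
    return Resolution(
        sample_id, genotype, ResolutionStatus.UNRESOLVED, single_matches=singles
    )


def pedigree_filter(
    child_pairs: Sequence[HaplotypePair],
    father_pairs: Sequence[HaplotypePair],
    mother_pairs: Sequence[HaplotypePair],
) -> list[HaplotypePair]:
    """Keep child pairs transmissible from the parents' candidate pairs.

    A child pair survives if one haplotype occurs in some paternal pair and
    the other in some maternal pair (in either orientation).  This is a
    simple Mendelian consistency screen, not full pedigree segregation.
    """
    father = {hid for p in father_pairs for hid in p.ids}
    mother = {hid for p in mother_pairs for hid in p.ids}
    kept = []
    for pair in child_pairs:
        h1, h2 = pair.ids
        if (h1 in father and h2 in mother) or (h1 in mother and h2 in father):
            kept.append(pair)
    return kept


# ---------------------------------------------------------------------------
# projection from assay-level calls to library loci


def project_genotype(
    marker_cn: Mapping[str, int],
    panel,
    marker_order: Sequence[str],
) -> tuple[tuple[int, ...] | None, list[str]]:
    """Collapse per-assay copy numbers onto the library's gene-level loci.

    Genes typed by two assays (paired assays) take the consensus value; a
    discordant pair blocks haplotype inference for the sample (returns
    ``(None, [discordant genes])``) because the genotype vector is then
    ambiguous.  Sum-rule total assays are consistency checks only and are
    not projected.
    """
    totals = panel.sum_rule_totals
    by_gene: dict[str, list[int]] = {}
    for m in panel.target_markers:
        if m.marker_id in totals:
            continue
        if m.marker_id in marker_cn:
            by_gene.setdefault(m.gene, []).append(int(marker_cn[m.marker_id]))
    discordant = [g for g, vals in by_gene.items() if len(set(vals)) > 1]
    if discordant:
        return None, sorted(discordant)
    vector = []
    for locus in marker_order:
        vals = by_gene.get(locus)
        if not vals:
            return None, [f"missing:{locus}"]
        vector.append(vals[0])
    return tuple(vector), []
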