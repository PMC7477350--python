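"""Reduced mutant-proteoform search-database construction.

Each single-amino-acid variant becomes one FASTA entry named
``NX_<accession>-<ref><pos><alt>`` holding the mutated tryptic peptide
that carries the substitution plus up to two fully-cleaved tryptic
peptides of flanking context on each side (truncated at the protein
termini). Keeping only this window, rather than the whole mutated
protein, keeps a database of hundreds of thousands of substitutions
searchable while still covering every peptide with up to two missed
cleavages that contains the variant residue.

Digestion follows trypsin specificity: cleavage C-terminal to K or R,
by default suppressed when the next residue is proline (the Keil rule).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from saavkit.core_io import ProteinRecord, SaavkitError, VariantRecord

log = logging.getLogger("saavkit.saav_db")


class ReferenceMismatchError(SaavkitError):
    pass


@dataclass(frozen=True)
class Peptide:
    """A digestion product with 1-based inclusive coordinates on its parent."""

    sequence: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(f"coordinates [{self.start},{self.end}] do not fit {self.sequence!r}")


@dataclass(frozen=True)
class MutantDbEntry:
    """One reduced mutant-context database entry.

    ``offset`` is the 1-based position, on the full mutated protein, of
    the first residue of ``sequence``; the variant residue therefore sits
    at local position ``variant.position - offset + 1``.
    """

    name: str
    sequence: str
    parent_accession: str
    offset: int
    variant: VariantRecord

    @property
    def variant_local_position(self) -> int:
        return self.variant.position - self.offset + 1


def cleavage_sites(sequence: str, proline_rule: bool = True) -> list[int]:
    """0-based indices i such that trypsin cuts between sequence[i] and sequence[i+1]."""
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and not (proline_rule and sequence[i + 1] == "P"):
            sites.append(i)
    return sites


def digest(sequence: str, missed_cleavages: int = 0, proline_rule: bool = True) -> list[Peptide]:
    """In-silico tryptic digestion.

    With ``missed_cleavages = 0`` returns the fully-cleaved peptides,
    which tile the sequence without gaps or overlaps. With ``m > 0``
    additionally returns every concatenation of up to ``m + 1``
    consecutive fully-cleaved peptides, ordered by start then length.
    """
    if not sequence:
        return []
    bounds = [0] + [i + 1 for i in cleavage_sites(sequence, proline_rule)] + [len(sequence)]
    base = [
        Peptide(sequence[bounds[i] : bounds[i + 1]], bounds[i] + 1, bounds[i + 1])
        for i in range(len(bounds) - 1)
    ]
    if missed_cleavages == 0:
        return base
    out = []
    for i in range(len(base)):
        for j in range(i, min(i + missed_cleavages + 1, len(base))):
            out.append(
                Peptide(
                    "".join(p.sequence for p in base[i : j + 1]),
                    base[i].start,
                    base[j].end,
                )
            )
    return out


def apply_variant(protein: ProteinRecord, variant: VariantRecord) -> str:
    """Return the full protein sequence with the single substitution applied.

    Raises :class:`ReferenceMismatchError` when the canonical residue at
    the variant position does not equal ``ref_aa`` — public variant
    catalogs are noisy, so batch callers skip and report these.
    """
    if variant.position > len(protein.sequence):
        raise SaavkitError(
            f"{variant.accession} {variant.short_label}: position out of range "
            f"(protein length {len(protein.sequence)})"
        )
    found = protein.sequence[variant.position - 1]
    if found != variant.ref_aa:
        raise ReferenceMismatchError(
            f"{variant.accession} {variant.short_label}: reference mismatch, "
            f"canonical residue is {found!r}"
        )
    return (
        protein.sequence[: variant.position - 1]
        + variant.alt_aa
        + protein.sequence[variant.position :]
    )


def entry_name(accession: str, variant: VariantRecord) -> str:
    return f"NX_{accession}-{variant.short_label}"


_NAME_RE = re.compile(r"^NX_(?P<acc>.+)-(?P<ref>[A-Z])(?P<pos>\d+)(?P<alt>[A-Z])$")


def parse_entry_name(name: str) -> tuple[str, VariantRecord]:
    """Invert :func:`entry_name`: recover (accession, variant) from an entry name."""
    m = _NAME_RE.match(name)
    if m is None:
        raise SaavkitError(f"unparseable entry name {name!r}")
    return m.group("acc"), VariantRecord(
        m.group("acc"), int(m.group("pos")), m.group("ref"), m.group("alt")
    )


def build_entry(
    protein: ProteinRecord,
    variant: VariantRecord,
    flank_peptides: int = 2,
    proline_rule: bool = True,
) -> MutantDbEntry:
    """Build the reduced mutant-context entry for one variant.

    The mutated protein is digested fully (no missed cleavages; the
    substitution may create or destroy a K/R site, so the mutated
    sequence defines the peptide boundaries). The entry is the peptide
    containing the variant plus up to ``flank_peptides`` peptides on
    each side, truncated at the protein termini.
    """
    mutated = apply_variant(protein, variant)
    peptides = digest(mutated, missed_cleavages=0, proline_rule=proline_rule)
    hit = next(i for i, p in enumerate(peptides) if p.start <= variant.position <= p.end)
    lo = max(0, hit - flank_peptides)
    hi = min(len(peptides) - 1, hit + flank_peptides)
    window = peptides[lo : hi + 1]
    return MutantDbEntry(
        name=entry_name(protein.accession, variant),
        sequence="".join(p.sequence for p in window),
        parent_accession=protein.accession,
        offset=window[0].start,
        variant=variant,
    )


@dataclass
class BuildReport:
    """Count conservation: variants_in = written + excluded + mismatched + duplicates + unresolvable."""

    variants_in: int = 0
    entries_written: int = 0
    skipped_excluded: int = 0
    reference_mismatches: int = 0
    duplicates_collapsed: int = 0
    unresolvable_accessions: int = 0

    def conserved(self) -> bool:
        return self.variants_in == (
            self.entries_written
            + self.skipped_excluded
            + self.reference_mismatches
            + self.duplicates_collapsed
            + self.unresolvable_accessions
        )


def build_database(
    proteome: Sequence[ProteinRecord],
    variants: Sequence[VariantRecord],
    excluded_accessions: Iterable[str] = (),
    contaminants: Sequence[ProteinRecord] = (),
    include_consensus: bool = False,
    flank_peptides: int = 2,
    proline_rule: bool = True,
) -> tuple[list[ProteinRecord], list[MutantDbEntry], BuildReport]:
    """Build the search database: mutant entries (+ optional consensus, + contaminants).

    Deterministic: entries follow input variant order; duplicates
    (same accession+position+alt) collapse to one entry; excluded
    accessions (e.g. titin Q8WZ42, which alone carries tens of
    thousands of catalogued substitutions) are counted but skipped.

    Returns (FASTA records in output order, mutant entries, report).
    Entry headers carry ``parent=`` and ``offset=`` so downstream
    filtering can recover coordinates without a sidecar file.
    """
    excluded = set(excluded_accessions)
    by_acc: Mapping[str, ProteinRecord] = {p.accession: p for p in proteome}
    report = BuildReport(variants_in=len(variants))
    entries: list[MutantDbEntry] = []
    seen: set[str] = set()
    for v in variants:
        if v.accession in excluded:
            report.skipped_excluded += 1
            continue
        protein = by_acc.get(v.accession)
        if protein is None:
            log.warning("variant %s %s: accession not in proteome", v.accession, v.short_label)
            report.unresolvable_accessions += 1
            continue
        name = entry_name(v.accession, v)
        if name in seen:
            report.duplicates_collapsed += 1
            continue
        try:
            entry = build_entry(protein, v, flank_peptides, proline_rule)
        except ReferenceMismatchError as exc:
            log.warning("%s", exc)
            report.reference_mismatches += 1
            continue
        seen.add(name)
        entries.append(entry)
        report.entries_written += 1

    records = [
        ProteinRecord(
            accession=e.name,
            sequence=e.sequence,
            description=f"{e.name} parent={e.parent_accession} offset={e.offset}",
        )
        for e in entries
    ]
    if include_consensus:
        records.extend(proteome)
    records.extend(contaminants)
    return records, entries, report


class CanonicalPeptideIndex:
    """Exact-membership index over every tryptic peptide of a canonical proteome.

    Answers "is this peptide sequence produced by digestion (up to
    ``missed_cleavages``) of ANY canonical protein?" — the operational
    definition of a peptide that is *not* mutant-specific. A parallel
    I/L-collapsed index supports isobaric-aware membership, since
    isoleucine and leucine are indistinguishable by mass.
    """

    def __init__(
        self,
        proteome: Iterable[ProteinRecord],
        missed_cleavages: int = 2,
        proline_rule: bool = True,
    ) -> None:
        self.missed_cleavages = missed_cleavages
        self.proline_rule = proline_rule
        self._exact: set[str] = set()
        self._il: set[str] = set()
        for protein in proteome:
            for pep in digest(protein.sequence, missed_cleavages, proline_rule):
                self._exact.add(pep.sequence)
                self._il.add(collapse_il(pep.sequence))

    def __contains__(self, peptide: str) -> bool:
        return peptide in self._exact

    def contains(self, peptide: str, il_equivalence: bool = False) -> bool:
        if il_equivalence:
            return collapse_il(peptide) in self._il
        return peptide in self._exact

    def __len__(self) -> int:
        return len(self._exact)


def collapse_il(sequence: str) -> str:
    """Map I and L to one symbol (J), the standard isobaric collapse."""
    return sequence.replace("I", "J").replace("L", "J")


def canonical_peptide_index(
    proteome: Iterable[ProteinRecord],
    missed_cleavages: int = 2,
    proline_rule: bool = True,
) -> CanonicalPeptideIndex:
    return CanonicalPeptideIndex(proteome, missed_cleavages, proline_rule)
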