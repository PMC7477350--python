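"""Filtering of raw PSM exports down to reliable mutant-proteoform evidence.

A peptide-spectrum match counts as reliable evidence for a mutant
proteoform only when all of the following hold:

* the peptide is fully tryptic (both termini at K/R cleavage boundaries
  or protein termini, at most ``max_missed`` internal missed cleavages);
* its span on the matched entry covers the substituted residue;
* its sequence is mutant-specific — not produced by tryptic digestion
  of any canonical protein (optionally testing after collapsing the
  isobaric pair I/L, which standard fragmentation cannot distinguish);
* the match is unambiguous — assigned to one entry, or to several
  isoform entries of one parent carrying the same amino-acid exchange
  (merged into one entry group). Matches spread across different
  parents or different exchanges are discarded.

I<->L substitutions pass all sequence-level checks yet are isobaric with
the canonical residue; they are kept but flagged for later experimental
verification rather than silently trusted.

Rejections are applied in a fixed order (non-tryptic, then
not-covering, then not-specific, then ambiguous) so reason codes are
deterministic; each PSM's verdict is independent of every other PSM.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from saavkit.core_io import PSMRecord, SampleMetadata, SaavkitError, TERMINUS
from saavkit.saav_db import CanonicalPeptideIndex, MutantDbEntry, cleavage_sites

log = logging.getLogger("saavkit.psm_filter")

KEPT = "kept"
KEPT_ISOBARIC = "kept_isobaric_flagged"
REJ_NONTRYPTIC = "rejected_nontryptic"
REJ_NOT_COVERING = "rejected_not_covering"
REJ_NOT_SPECIFIC = "rejected_not_specific"
REJ_AMBIGUOUS = "rejected_ambiguous"
DECISIONS = (KEPT, KEPT_ISOBARIC, REJ_NONTRYPTIC, REJ_NOT_COVERING, REJ_NOT_SPECIFIC, REJ_AMBIGUOUS)


@dataclass(frozen=True)
class FilterVerdict:
    psm: PSMRecord
    decision: str
    grouped_entry_names: tuple[str, ...] = ()
    notes: str = ""

    @property
    def kept(self) -> bool:
        return self.decision in (KEPT, KEPT_ISOBARIC)


@dataclass
class MutantEvidence:
    """Per-sample spectral-count evidence for one mutant entry group."""

    sample_id: str
    entry_group: str
    member_names: tuple[str, ...]
    spectral_count: int
    replicate_presence: dict[str, bool] = field(default_factory=dict)
    isobaric_flag: bool = False


def is_tryptic(psm: PSMRecord, max_missed: int = 2, proline_rule: bool = True) -> bool:
    """Fully-tryptic test on flanking context and internal missed cleavages.

    N-terminal boundary: preceding residue is K/R (and, under the
    proline rule, the peptide does not start with P) or the protein
    start. C-terminal boundary: peptide ends in K/R or the protein end.
    Internal K/R (proline-rule aware) count as missed cleavages.
    """
    pep = psm.peptide
    if psm.preceding_aa == TERMINUS:
        n_ok = True
    else:
        n_ok = psm.preceding_aa in "KR" and not (proline_rule and pep[0] == "P")
    c_ok = pep[-1] in "KR" or psm.following_aa == TERMINUS
    if not (n_ok and c_ok):
        return False
    return len(cleavage_sites(pep, proline_rule)) <= max_missed


def covers_variant(psm: PSMRecord, entry: MutantDbEntry) -> bool:
    """True iff some occurrence of the peptide in the entry spans the variant residue."""
    target = entry.variant_local_position
    hit = False
    for m in re.finditer(f"(?={re.escape(psm.peptide)})", entry.sequence):
        start = m.start() + 1  # 1-based on entry
        hit = True
        if start <= target <= start + len(psm.peptide) - 1:
            return True
    if not hit:
        raise SaavkitError(
            f"mapping inconsistency: peptide {psm.peptide!r} not found in entry {entry.name}"
        )
    return False


def is_mutant_specific(
    peptide: str, canonical_index: CanonicalPeptideIndex, il_equivalence: bool = True
) -> bool:
    """True iff the peptide is absent from the canonical tryptic peptide index."""
    return not canonical_index.contains(peptide, il_equivalence=il_equivalence)


def flag_isobaric(variant) -> bool:
    """I<->L exchanges are mass-identical and undecidable by fragmentation."""
    return {variant.ref_aa, variant.alt_aa} == {"I", "L"}


_ISOFORM_SUFFIX = re.compile(r"-\d+$")


def _isoform_root(accession: str) -> str:
    return _ISOFORM_SUFFIX.sub("", accession)


def resolve_ambiguity(
    psm: PSMRecord,
    entry_catalog: Mapping[str, MutantDbEntry],
    isoform_map: Mapping[str, str] | None = None,
) -> tuple[bool, tuple[str, ...]]:
    """Decide whether a multi-entry match is a benign isoform group.

    Matches to several entries are kept only when every entry belongs to
    isoforms of one parent (accession root, overridable via
    ``isoform_map``) and carries the same amino-acid exchange; the
    entries then merge into one group. Returns (kept, sorted group names).
    """
    keys = set()
    for name in psm.matched_entries:
        entry = entry_catalog.get(name)
        if entry is None:
            raise SaavkitError(f"unknown database entry {name!r}")
        root = (isoform_map or {}).get(entry.parent_accession) or _isoform_root(
            entry.parent_accession
        )
        keys.add((root, entry.variant.short_label))
    return len(keys) == 1, tuple(sorted(set(psm.matched_entries)))


@dataclass
class FilterSettings:
    max_missed: int = 2
    proline_rule: bool = True
    il_equivalence: bool = True
    isoform_map: Mapping[str, str] | None = None
    warn_deamidation_mimics: bool = False


def filter_psms(
    psms: Iterable[PSMRecord],
    entries: Sequence[MutantDbEntry],
    canonical_index: CanonicalPeptideIndex,
    settings: FilterSettings | None = None,
) -> list[FilterVerdict]:
    """Apply the full filtering cascade; every PSM receives exactly one verdict."""
    settings = settings or FilterSettings()
    catalog = {e.name: e for e in entries}
    verdicts: list[FilterVerdict] = []
    for psm in psms:
        if not is_tryptic(psm, settings.max_missed, settings.proline_rule):
            verdicts.append(FilterVerdict(psm, REJ_NONTRYPTIC))
            continue
        matched = [catalog[n] for n in psm.matched_entries if n in catalog]
        if len(matched) < len(psm.matched_entries):
            missing = [n for n in psm.matched_entries if n not in catalog]
            raise SaavkitError(f"unknown database entry {missing[0]!r}")
        covered = []
        errors = 0
        for e in matched:
            try:
                covered.append(covers_variant(psm, e))
            except SaavkitError:
                # engine-claimed match absent from this entry; benign if
                # the peptide is locatable in at least one matched entry
                errors += 1
        if errors == len(matched):
            raise SaavkitError(
                f"mapping inconsistency: peptide {psm.peptide!r} not found in any matched entry"
            )
        if not any(covered):
            verdicts.append(FilterVerdict(psm, REJ_NOT_COVERING))
            continue
        isobaric = any(flag_isobaric(e.variant) for e in matched)
        # An I<->L exchange is mass-identical to the canonical residue, so
        # the I/L-collapsed index would always absorb it; such matches are
        # held to exact-sequence specificity and kept flagged instead.
        il_check = settings.il_equivalence and not isobaric
        if not is_mutant_specific(psm.peptide, canonical_index, il_check):
            verdicts.append(FilterVerdict(psm, REJ_NOT_SPECIFIC))
            continue
        kept, group = resolve_ambiguity(psm, catalog, settings.isoform_map)
        if not kept:
            verdicts.append(FilterVerdict(psm, REJ_AMBIGUOUS, group))
            continue
        notes = ""
        if settings.warn_deamidation_mimics:
            v = matched[0].variant
            if (v.ref_aa, v.alt_aa) in (("N", "D"), ("Q", "E")):
                notes = "deamidation-mimic exchange"
        verdicts.append(FilterVerdict(psm, KEPT_ISOBARIC if isobaric else KEPT, group, notes))
    counts: dict[str, int] = {}
    for v in verdicts:
        counts[v.decision] = counts.get(v.decision, 0) + 1
    log.info("filter verdicts: %s", counts)
    return verdicts


def _group_representative(group: tuple[str, ...]) -> str:
    return min(group)


def combine_replicates(
    verdicts: Iterable[FilterVerdict],
    metadata: Sequence[SampleMetadata],
) -> list[MutantEvidence]:
    """Merge kept PSMs across technical replicates into per-sample evidence.

    Spectral counts are summed (replicates are searched together, not
    averaged); presence is recorded per replicate. Entry groups with no
    kept PSM in a sample are absent from the output.
    """
    known = {m.sample_id for m in metadata}
    acc: dict[tuple[str, str], MutantEvidence] = {}
    for v in verdicts:
        if not v.kept:
            continue
        psm = v.psm
        if psm.sample_id not in known:
            raise SaavkitError(f"sample {psm.sample_id!r} missing from metadata")
        rep = _group_representative(v.grouped_entry_names)
        key = (psm.sample_id, rep)
        ev = acc.get(key)
        if ev is None:
            ev = MutantEvidence(psm.sample_id, rep, v.grouped_entry_names, 0)
            acc[key] = ev
        ev.spectral_count += psm.count
        ev.replicate_presence[psm.replicate_id] = True
        if v.decision == KEPT_ISOBARIC:
            ev.isobaric_flag = True
    return [acc[k] for k in sorted(acc)]
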