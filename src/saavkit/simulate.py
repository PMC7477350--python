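"""Synthetic study generator with a machine-readable truth record.

Generates every input the pipeline consumes — a small proteome, a
variant catalog, per-sample PSM tables containing both valid mutant
PSMs and planted violations of each filtering rule, sample metadata,
and block-correlated expression matrices — so that every downstream
result can be checked against known ground truth.

What the generator emulates: trypsin-digestible protein sequences
(K/R-enriched residue composition), reference-consistent substitutions
with a tunable isobaric (I<->L) fraction, overdispersed sparse spectral
counts (negative binomial, split multinomially across technical
replicates), the four violation classes the filter must reject
(non-tryptic termini, peptides not covering the substitution,
sequences shared with the canonical proteome, multi-parent ambiguous
matches), and coexpression structure as shared latent factors per
module. Peptides shared with the canonical proteome are planted by
adding "shadow" canonical proteins that carry a copy of a variant
peptide, the way a paralog would.

All randomness flows through one seeded numpy Generator, so one seed
reproduces every artifact byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from saavkit.core_io import (
    ProteinRecord,
    PSMRecord,
    SampleMetadata,
    TERMINUS,
    VariantRecord,
    write_fasta,
    write_metadata_table,
)
from saavkit.saav_db import (
    CanonicalPeptideIndex,
    MutantDbEntry,
    apply_variant,
    build_database,
    collapse_il,
    digest,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

VALID = "valid"
ISOBARIC = "isobaric"
NONTRYPTIC = "nontryptic"
NOT_COVERING = "not_covering"
NOT_SPECIFIC = "not_specific"
AMBIGUOUS = "ambiguous"
PSM_CLASSES = (VALID, ISOBARIC, NONTRYPTIC, NOT_COVERING, NOT_SPECIFIC, AMBIGUOUS)


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (100, 400),
    seed: int | np.random.Generator = 0,
) -> list[ProteinRecord]:
    """Random proteome with K/R-boosted composition so digestion yields peptides.

    K and R each get 8% frequency (the remaining 18 residues share the
    rest uniformly); every protein is regenerated until it digests into
    at least 3 fully-cleaved peptides.
    """
    rng = _rng(seed)
    weights = np.full(20, 0.84 / 18)
    weights[AMINO_ACIDS.index("K")] = 0.08
    weights[AMINO_ACIDS.index("R")] = 0.08
    letters = np.array(list(AMINO_ACIDS))
    out = []
    for i in range(n_proteins):
        for _ in range(100):
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            seq = "".join(rng.choice(letters, size=length, p=weights))
            if len(digest(seq)) >= 3:
                break
        out.append(ProteinRecord(f"P{i + 1:04d}", seq, f"P{i + 1:04d} synthetic protein"))
    return out


def simulate_variants(
    proteome: Sequence[ProteinRecord],
    n_variants: int,
    il_fraction: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> list[VariantRecord]:
    """Reference-consistent substitutions at distinct (protein, position) sites.

    ``il_fraction`` of the variants are I<->L exchanges (placed at I/L
    residues); the rest never form an isobaric pair.
    """
    rng = _rng(seed)
    sites = [(p.accession, i + 1, aa) for p in proteome for i, aa in enumerate(p.sequence)]
    if n_variants > len(sites):
        raise ValueError("more variants requested than residues available")
    il_sites = [s for s in sites if s[2] in "IL"]
    n_il = min(int(round(n_variants * il_fraction)), len(il_sites))
    variants: list[VariantRecord] = []
    used: set[tuple[str, int]] = set()
    idx = rng.permutation(len(il_sites))
    for j in idx[:n_il]:
        acc, pos, ref = il_sites[j]
        variants.append(VariantRecord(acc, pos, ref, "L" if ref == "I" else "I"))
        used.add((acc, pos))
    idx = rng.permutation(len(sites))
    for j in idx:
        if len(variants) == n_variants:
            break
        acc, pos, ref = sites[j]
        if (acc, pos) in used:
            continue
        choices = [aa for aa in AMINO_ACIDS if aa != ref and {ref, aa} != {"I", "L"}]
        variants.append(VariantRecord(acc, pos, ref, str(rng.choice(choices))))
        used.add((acc, pos))
    return variants


@dataclass
class PsmDesign:
    """Study design for the PSM generator.

    ``traits`` maps trait name to number of biological samples (the
    default mirrors a 9/9/18 three-trait cohort of 36 samples, each
    acquired as technical triplicates). Spectral counts per detected
    entry follow a negative binomial with the given mean and dispersion
    (variance = mean + dispersion * mean^2), split multinomially across
    replicates. ``violation_rates`` are fractions of the per-sample
    valid PSM rows planted as each violation class.
    """

    traits: Mapping[str, int] = field(default_factory=lambda: {"M1": 9, "M2": 9, "NM": 18})
    replicates: int = 3
    detect_prob: float = 0.4
    nb_mean: float = 3.0
    nb_dispersion: float = 0.5
    violation_rates: Mapping[str, float] = field(
        default_factory=lambda: {NONTRYPTIC: 0.05, NOT_COVERING: 0.05, NOT_SPECIFIC: 0.05, AMBIGUOUS: 0.05}
    )
    max_missed: int = 2
    proline_rule: bool = True


@dataclass
class SimulationTruth:
    """Ground truth for one simulated study."""

    seed: int
    params: dict
    variants: list[VariantRecord]
    psm_classes: dict[str, str]  # scan_id -> class
    true_counts: dict[tuple[str, str], int]  # (sample_id, entry_name) -> kept count
    reserved_nonspecific_entries: list[str]

    def count_matrix(self) -> pd.DataFrame:
        samples = sorted({s for s, _ in self.true_counts})
        entries = sorted({e for _, e in self.true_counts})
        df = pd.DataFrame(0, index=entries, columns=samples, dtype=int)
        for (s, e), c in self.true_counts.items():
            df.loc[e, s] = c
        return df


@dataclass
class PsmSimulation:
    psms: list[PSMRecord]
    metadata: list[SampleMetadata]
    shadow_proteins: list[ProteinRecord]
    truth: SimulationTruth


def _flanks(mutated: str, start: int, end: int) -> tuple[str, str]:
    """Flanking residues for a peptide spanning 1-based [start, end] of ``mutated``."""
    pre = mutated[start - 2] if start > 1 else TERMINUS
    post = mutated[end] if end < len(mutated) else TERMINUS
    return pre, post


def _covering_candidates(
    entry: MutantDbEntry,
    mutated: str,
    design: PsmDesign,
) -> list[tuple[str, int, int]]:
    """Tryptic peptides (<= max_missed) of the mutated protein that cover the
    variant and lie inside the entry window. Returns (sequence, start, end)."""
    out = []
    lo, hi = entry.offset, entry.offset + len(entry.sequence) - 1
    for pep in digest(mutated, design.max_missed, design.proline_rule):
        if pep.start >= lo and pep.end <= hi and pep.start <= entry.variant.position <= pep.end:
            out.append((pep.sequence, pep.start, pep.end))
    return out


def _occurs_covering(peptide: str, entry: MutantDbEntry) -> bool:
    target = entry.variant_local_position
    start = entry.sequence.find(peptide)
    while start != -1:
        if start + 1 <= target <= start + len(peptide):
            return True
        start = entry.sequence.find(peptide, start + 1)
    return False


def simulate_psms(
    proteome: Sequence[ProteinRecord],
    entries: Sequence[MutantDbEntry],
    design: PsmDesign | None = None,
    seed: int | np.random.Generator = 0,
) -> PsmSimulation:
    """Generate per-sample PSM tables with planted validity classes.

    Valid rows are tryptic, variant-covering, mutant-specific peptides
    of the mutated sequences; violations are planted at the design's
    rates with their class recorded in the truth record. Entries used to
    plant canonical-shared (not-specific) peptides are reserved and
    contribute no valid rows.
    """
    design = design or PsmDesign()
    rng = _rng(seed)
    seed_value = int(seed) if not isinstance(seed, np.random.Generator) else -1

    mutated_seqs = {}
    by_acc = {p.accession: p for p in proteome}
    for e in entries:
        mutated_seqs[e.name] = apply_variant(by_acc[e.parent_accession], e.variant)

    candidates = {
        e.name: _covering_candidates(e, mutated_seqs[e.name], design) for e in entries
    }
    usable = [e for e in entries if candidates[e.name]]

    # Reserve some non-isobaric entries to plant canonical-shared peptides:
    # a shadow protein carries a copy of one variant peptide, so the
    # peptide stops being mutant-specific.
    nonisobaric = [
        e for e in usable
        if {e.variant.ref_aa, e.variant.alt_aa} != {"I", "L"}
    ]
    n_reserved = min(len(nonisobaric) // 10 + 1, len(nonisobaric)) if design.violation_rates.get(NOT_SPECIFIC, 0) > 0 else 0
    reserved = list(rng.choice(len(nonisobaric), size=n_reserved, replace=False)) if n_reserved else []
    reserved_entries = [nonisobaric[i] for i in sorted(int(i) for i in reserved)]
    reserved_names = {e.name for e in reserved_entries}

    shadow_proteins: list[ProteinRecord] = []
    shadow_peptide: dict[str, tuple[str, int, int]] = {}
    for i, e in enumerate(reserved_entries):
        cands = [c for c in candidates[e.name] if c[0][0] != "P"]
        if not cands:
            reserved_names.discard(e.name)
            continue
        pep, start, end = cands[int(rng.integers(len(cands)))]
        if pep[-1] in "KR":
            seq = "MK" + pep + "AGTE"
        else:
            seq = "MK" + pep
        acc = f"SHADOW{i + 1:03d}"
        shadow_proteins.append(ProteinRecord(acc, seq, f"{acc} synthetic paralog decoy"))
        shadow_peptide[e.name] = (pep, start, end)

    index = CanonicalPeptideIndex(
        list(proteome) + shadow_proteins, design.max_missed, design.proline_rule
    )

    # Specific candidates per entry: absent from the canonical+shadow index
    # (I/L-collapsed for non-isobaric variants, exact for isobaric ones).
    specific: dict[str, list[tuple[str, int, int]]] = {}
    for e in usable:
        if e.name in reserved_names:
            continue
        isobaric = {e.variant.ref_aa, e.variant.alt_aa} == {"I", "L"}
        keep = []
        for pep, start, end in candidates[e.name]:
            if index.contains(pep, il_equivalence=not isobaric):
                continue
            keep.append((pep, start, end))
        if keep:
            specific[e.name] = keep
    emitters = [e for e in usable if e.name in specific]
    entry_by_name = {e.name: e for e in entries}

    samples: list[SampleMetadata] = []
    for trait, count in design.traits.items():
        for i in range(count):
            samples.append(SampleMetadata(f"S_{trait}_{i + 1:02d}", trait))

    nb_n = 1.0 / design.nb_dispersion
    nb_p = nb_n / (nb_n + design.nb_mean)

    psms: list[PSMRecord] = []
    psm_classes: dict[str, str] = {}
    true_counts: dict[tuple[str, str], int] = {}
    scan = 0

    def emit(sample, replicate, pep, pre, post, matched, count, cls):
        nonlocal scan
        scan += 1
        sid = f"scan{scan:07d}"
        psms.append(
            PSMRecord(
                sample_id=sample,
                replicate_id=replicate,
                peptide=pep,
                preceding_aa=pre,
                following_aa=post,
                matched_entries=tuple(matched),
                scan_id=sid,
                count=int(count),
            )
        )
        psm_classes[sid] = cls

    for meta in samples:
        sample = meta.sample_id
        n_valid_rows = 0
        for e in emitters:
            if rng.random() > design.detect_prob:
                continue
            total = int(rng.negative_binomial(nb_n, nb_p))
            if total == 0:
                continue
            mutated = mutated_seqs[e.name]
            isobaric = {e.variant.ref_aa, e.variant.alt_aa} == {"I", "L"}
            cls = ISOBARIC if isobaric else VALID
            split = rng.multinomial(total, np.full(design.replicates, 1.0 / design.replicates))
            for r, share in enumerate(split):
                if share == 0:
                    continue
                pep, start, end = specific[e.name][int(rng.integers(len(specific[e.name])))]
                pre, post = _flanks(mutated, start, end)
                emit(sample, f"rep{r + 1}", pep, pre, post, [e.name], share, cls)
                n_valid_rows += 1
            true_counts[(sample, e.name)] = true_counts.get((sample, e.name), 0) + total

        # planted violations, deterministically sized from the valid row count
        for cls, rate in design.violation_rates.items():
            n_plant = int(round(rate * n_valid_rows))
            planted = 0
            attempts = 0
            while planted < n_plant and attempts < 50 * n_plant + 50:
                attempts += 1
                e = emitters[int(rng.integers(len(emitters)))] if cls != NOT_SPECIFIC else None
                rep = f"rep{int(rng.integers(design.replicates)) + 1}"
                if cls == NONTRYPTIC:
                    cands = [
                        (p, s, en) for p, s, en in specific[e.name]
                        if s > 1 and p[0] not in "KR" and s < e.variant.position and len(p) > 2
                    ]
                    if not cands:
                        continue
                    pep, start, end = cands[int(rng.integers(len(cands)))]
                    mutated = mutated_seqs[e.name]
                    trimmed = pep[1:]
                    if not _occurs_covering(trimmed, e):
                        continue
                    pre, post = pep[0], _flanks(mutated, start, end)[1]
                    emit(sample, rep, trimmed, pre, post, [e.name], 1, NONTRYPTIC)
                elif cls == NOT_COVERING:
                    mutated = mutated_seqs[e.name]
                    lo, hi = e.offset, e.offset + len(e.sequence) - 1
                    flanks = [
                        p for p in digest(mutated, 0, design.proline_rule)
                        if p.start >= lo and p.end <= hi
                        and not (p.start <= e.variant.position <= p.end)
                        and not _occurs_covering(p.sequence, e)
                    ]
                    if not flanks:
                        continue
                    p = flanks[int(rng.integers(len(flanks)))]
                    pre, post = _flanks(mutated, p.start, p.end)
                    emit(sample, rep, p.sequence, pre, post, [e.name], 1, NOT_COVERING)
                elif cls == NOT_SPECIFIC:
                    if not shadow_peptide:
                        break
                    name = sorted(shadow_peptide)[int(rng.integers(len(shadow_peptide)))]
                    pep, start, end = shadow_peptide[name]
                    mutated = mutated_seqs[name]
                    pre, post = _flanks(mutated, start, end)
                    emit(sample, rep, pep, pre, post, [name], 1, NOT_SPECIFIC)
                elif cls == AMBIGUOUS:
                    others = [o for o in emitters if entry_by_name[o.name].parent_accession != e.parent_accession]
                    if not others:
                        continue
                    other = others[int(rng.integers(len(others)))]
                    pep, start, end = specific[e.name][int(rng.integers(len(specific[e.name])))]
                    pre, post = _flanks(mutated_seqs[e.name], start, end)
                    emit(sample, rep, pep, pre, post, [e.name, other.name], 1, AMBIGUOUS)
                planted += 1

    truth = SimulationTruth(
        seed=seed_value,
        params={
            "traits": dict(design.traits),
            "replicates": design.replicates,
            "detect_prob": design.detect_prob,
            "nb_mean": design.nb_mean,
            "nb_dispersion": design.nb_dispersion,
            "violation_rates": dict(design.violation_rates),
        },
        variants=[e.variant for e in entries],
        psm_classes=psm_classes,
        true_counts=true_counts,
        reserved_nonspecific_entries=sorted(reserved_names),
    )
    return PsmSimulation(psms, samples, shadow_proteins, truth)


@dataclass
class ModuleMatrixSimulation:
    expression: pd.DataFrame  # proteins x samples
    metadata: list[SampleMetadata]
    labels: dict[str, int]  # protein -> planted module id (0 = background)
    enriched_module: int
    planted_unique: dict[str, set[str]]  # trait -> planted group-unique protein set


def simulate_module_matrix(
    n_modules: int = 3,
    module_size: int = 40,
    n_background: int = 30,
    n_samples: int | None = None,
    traits: Mapping[str, int] | None = None,
    within_r: float = 0.8,
    noise_sd: float = 1.0,
    trait_shift: float = 1.5,
    seed: int | np.random.Generator = 0,
) -> ModuleMatrixSimulation:
    """Block-correlated expression matrix with planted module labels.

    Each module member's profile is sqrt(w) * latent + sqrt(1 - w) *
    noise_sd * eps, so the expected within-module correlation is
    w / (w + (1 - w) * noise_sd^2) — exactly ``within_r`` at the default
    noise_sd of 1, and 1 when noise_sd = 0. Background proteins are pure
    noise. Module 1's latent factor is shifted by ``trait_shift`` in the
    first trait's samples, and half of module 1's members form that
    trait's planted group-unique set (for ORA-recovery checks).
    """
    if not 0 < within_r < 1:
        raise ValueError("within_r must be in (0, 1)")
    rng = _rng(seed)
    traits = dict(traits or {"M1": 9, "M2": 9, "NM": 18})
    if n_samples is None:
        n_samples = sum(traits.values())
    if n_samples != sum(traits.values()):
        raise ValueError("n_samples inconsistent with trait design")
    metadata = []
    for trait, count in traits.items():
        for i in range(count):
            metadata.append(SampleMetadata(f"S_{trait}_{i + 1:02d}", trait))
    first_trait = next(iter(traits))
    shift_mask = np.array([m.trait == first_trait for m in metadata], dtype=float)

    names, rows, labels = [], [], {}
    w = np.sqrt(within_r)
    s = np.sqrt(1.0 - within_r) * noise_sd
    for m in range(1, n_modules + 1):
        latent = rng.standard_normal(n_samples)
        if m == 1:
            latent = latent + trait_shift * shift_mask
        for j in range(module_size):
            name = f"G{m:02d}_{j + 1:03d}"
            rows.append(w * latent + s * rng.standard_normal(n_samples))
            names.append(name)
            labels[name] = m
    for j in range(n_background):
        name = f"BG_{j + 1:03d}"
        rows.append(rng.standard_normal(n_samples))
        names.append(name)
        labels[name] = 0

    expression = pd.DataFrame(
        np.array(rows), index=names, columns=[m.sample_id for m in metadata]
    )
    module1 = [n for n, l in labels.items() if l == 1]
    planted_unique = {first_trait: set(module1[: module_size // 2])}
    return ModuleMatrixSimulation(expression, metadata, labels, 1, planted_unique)


# -- artifact writing ---------------------------------------------------------

def write_study(
    out_dir: str | Path,
    n_proteins: int = 50,
    n_variants: int = 300,
    il_fraction: float = 0.1,
    design: PsmDesign | None = None,
    seed: int = 17,
) -> dict[str, Path]:
    """Generate and write a full synthetic study: proteome FASTA, variant
    table, per-sample PSM tables, metadata, database FASTA and truth JSON.

    Deterministic: one seeded generator drives every artifact, so a
    seed regenerates the directory byte for byte.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    design = design or PsmDesign()

    proteome = simulate_proteome(n_proteins, seed=rng)
    variants = simulate_variants(proteome, n_variants, il_fraction, seed=rng)
    records, entries, report = build_database(proteome, variants)
    sim = simulate_psms(proteome, entries, design, seed=rng)

    paths = {
        "proteome": out_dir / "proteome.fasta",
        "variants": out_dir / "variants.tsv",
        "database": out_dir / "mutant_db.fasta",
        "metadata": out_dir / "metadata.tsv",
        "psms": out_dir / "psms.tsv",
        "truth": out_dir / "truth.json",
    }
    write_fasta(proteome + sim.shadow_proteins, paths["proteome"])
    pd.DataFrame(
        [
            {"accession": v.accession, "position": v.position, "ref_aa": v.ref_aa, "alt_aa": v.alt_aa}
            for v in variants
        ]
    ).to_csv(paths["variants"], sep="\t", index=False)
    write_fasta(records, paths["database"])
    write_metadata_table(sim.metadata, paths["metadata"])
    pd.DataFrame(
        [
            {
                "sample_id": p.sample_id,
                "replicate_id": p.replicate_id,
                "peptide": p.peptide,
                "preceding_aa": p.preceding_aa,
                "following_aa": p.following_aa,
                "matched_entries": ";".join(p.matched_entries),
                "scan_id": p.scan_id,
                "count": p.count,
            }
            for p in sim.psms
        ]
    ).to_csv(paths["psms"], sep="\t", index=False)
    truth = sim.truth
    paths["truth"].write_text(
        json.dumps(
            {
                "seed": seed,
                "params": truth.params,
                "build_report": vars(report),
                "psm_classes": truth.psm_classes,
                "true_counts": {f"{s}|{e}": c for (s, e), c in sorted(truth.true_counts.items())},
                "reserved_nonspecific_entries": truth.reserved_nonspecific_entries,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return paths
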