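"""Shared domain types, FASTA and delimited-table readers/writers, config and logging.

The toolkit's inputs are a canonical proteome (FASTA), a variant catalog
(one single-residue substitution per row), search-engine PSM exports
(one peptide-spectrum match per row) and a sample-metadata table mapping
samples to clinical traits. All readers are order-preserving and total:
every row yields exactly one record or one error that names the
offending record.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

log = logging.getLogger("saavkit")

#: The 20 standard one-letter amino-acid codes.
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
#: Additional codes tolerated when ``allow_nonstandard`` is set.
NONSTANDARD_AA = set("XUBZ")
#: Sentinel used in tables for a flanking residue at the protein terminus.
TERMINUS = "-"


class SaavkitError(Exception):
    """Base class for all toolkit errors."""


class InvalidResidueError(SaavkitError):
    pass


class TableFormatError(SaavkitError):
    pass


@dataclass(frozen=True)
class ProteinRecord:
    """One canonical protein: accession, description and residue sequence."""

    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidResidueError(f"{self.accession}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class VariantRecord:
    """One single-amino-acid variant on a canonical protein.

    ``position`` is 1-based on the canonical sequence, matching the
    NX_<accession>-<ref><pos><alt> naming convention.
    """

    accession: str
    position: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.accession}: position must be >= 1, got {self.position}")
        if self.ref_aa == self.alt_aa:
            raise ValueError(
                f"degenerate variant {self.accession} position {self.position}: "
                f"ref and alt are both {self.ref_aa!r}"
            )
        for aa in (self.ref_aa, self.alt_aa):
            if aa not in STANDARD_AA:
                raise InvalidResidueError(
                    f"{self.accession} position {self.position}: invalid residue {aa!r}"
                )

    @property
    def short_label(self) -> str:
        """e.g. ``S132L``."""
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match from a search-engine export.

    ``preceding_aa`` / ``following_aa`` hold the flanking residues of the
    peptide in its matched database entry, or ``"-"`` at a protein
    terminus. ``matched_entries`` lists the database entry names the
    engine assigned the spectrum to.
    """

    sample_id: str
    replicate_id: str
    peptide: str
    preceding_aa: str
    following_aa: str
    matched_entries: tuple[str, ...]
    scan_id: str = ""
    count: int = 1

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError(f"{self.sample_id}/{self.scan_id}: empty peptide")
        if not self.matched_entries:
            raise ValueError(f"{self.sample_id}/{self.scan_id}: no matched entries")
        if self.count < 1:
            raise ValueError(f"{self.sample_id}/{self.scan_id}: count must be >= 1")


@dataclass(frozen=True)
class SampleMetadata:
    """Sample-to-trait assignment (e.g. trait M1/M2/NM) plus free covariates."""

    sample_id: str
    trait: str
    covariates: Mapping[str, str] = field(default_factory=dict)


def _validate_sequence(accession: str, sequence: str, allow_nonstandard: bool) -> None:
    allowed = STANDARD_AA | (NONSTANDARD_AA if allow_nonstandard else set())
    for i, aa in enumerate(sequence, start=1):
        if aa not in allowed:
            raise InvalidResidueError(
                f"invalid residue {aa!r} in {accession} at position {i}"
            )
        if allow_nonstandard and aa in NONSTANDARD_AA:
            log.warning("nonstandard residue %s in %s at position %d", aa, accession, i)


def read_fasta(path: str | Path, allow_nonstandard: bool = False) -> list[ProteinRecord]:
    """Read a FASTA file into an ordered list of :class:`ProteinRecord`.

    Sequences are whitespace-stripped and uppercased. Raises on an empty
    file or on residues outside the standard 20-letter alphabet (unless
    ``allow_nonstandard``, which tolerates X/U/B/Z with a logged warning).
    """
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "")
        _validate_sequence(rec.id, seq, allow_nonstandard)
        records.append(ProteinRecord(accession=rec.id, sequence=seq, description=rec.description))
    if not records:
        raise TableFormatError(f"{path}: no records")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, line_width: int = 60) -> None:
    """Write records as FASTA with ``line_width``-column wrapped sequences.

    Round-trips with :func:`read_fasta`: accession, description and
    sequence survive unchanged.
    """
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.description if rec.description.startswith(rec.accession) else (
                f"{rec.accession} {rec.description}".strip()
            )
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), line_width):
                fh.write(rec.sequence[i : i + line_width] + "\n")


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read TSV (default) or CSV, sniffing the delimiter from the extension."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


VARIANT_COLUMNS = ("accession", "position", "ref_aa", "alt_aa")


def read_variant_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[VariantRecord]:
    """Read a variant catalog; duplicate rows (accession+position+alt) collapse with a warning.

    ``column_map`` renames file columns onto the required names
    ``accession, position, ref_aa, alt_aa``.
    """
    df = _read_table(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}")
    out: list[VariantRecord] = []
    seen: set[tuple[str, int, str]] = set()
    for idx, row in df.iterrows():
        try:
            pos = int(row["position"])
        except ValueError as exc:
            raise TableFormatError(f"{path} row {idx}: non-integer position {row['position']!r}") from exc
        rec = VariantRecord(row["accession"], pos, row["ref_aa"], row["alt_aa"])
        key = (rec.accession, rec.position, rec.alt_aa)
        if key in seen:
            log.warning("duplicate variant %s %s collapsed", rec.accession, rec.short_label)
            continue
        seen.add(key)
        out.append(rec)
    return out


_CONTEXT_RE = re.compile(r"^(?P<pre>[A-Z\-])\.(?P<pep>[A-Z]+)\.(?P<post>[A-Z\-])$")


def _parse_peptide_context(token: str) -> tuple[str, str, str]:
    """Split search-engine context notation ``K.PEPTIDER.A`` into (pre, core, post)."""
    m = _CONTEXT_RE.match(token)
    if m is None:
        return TERMINUS, token, TERMINUS
    return m.group("pre"), m.group("pep"), m.group("post")


PSM_DIALECTS = ("generic_tsv", "peaks_csv")


def read_psm_table(path: str | Path, dialect: str = "generic_tsv") -> list[PSMRecord]:
    """Read a PSM export into :class:`PSMRecord` rows.

    ``generic_tsv`` expects columns sample_id, replicate_id, peptide,
    preceding_aa, following_aa, matched_entries (semicolon-joined),
    scan_id and optional count. ``peaks_csv`` is a best-effort mapping of
    PEAKS-style exports: Peptide carries ``K.SEQ.R`` context notation and
    ``Accession`` is the semicolon-joined entry list.
    """
    if dialect not in PSM_DIALECTS:
        raise TableFormatError(f"unknown PSM dialect {dialect!r}; expected one of {PSM_DIALECTS}")
    df = _read_table(path)
    if dialect == "peaks_csv":
        rename = {
            "Sample": "sample_id",
            "Fraction": "replicate_id",
            "Peptide": "peptide",
            "Accession": "matched_entries",
            "Scan": "scan_id",
        }
        df = df.rename(columns=rename)
    required = ["sample_id", "replicate_id", "peptide", "matched_entries"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}")
    out: list[PSMRecord] = []
    for idx, row in df.iterrows():
        pep = row["peptide"]
        if "preceding_aa" in df.columns and "following_aa" in df.columns:
            pre, post = row["preceding_aa"] or TERMINUS, row["following_aa"] or TERMINUS
            if _CONTEXT_RE.match(pep):
                _, pep, _ = _parse_peptide_context(pep)
        else:
            pre, pep, post = _parse_peptide_context(pep)
        entries = tuple(e for e in str(row["matched_entries"]).split(";") if e)
        if not entries:
            raise TableFormatError(f"{path} row {idx}: empty matched_entries")
        count = int(row["count"]) if "count" in df.columns and row["count"] else 1
        out.append(
            PSMRecord(
                sample_id=row["sample_id"],
                replicate_id=row["replicate_id"],
                peptide=pep,
                preceding_aa=pre,
                following_aa=post,
                matched_entries=entries,
                scan_id=str(row.get("scan_id", idx)),
                count=count,
            )
        )
    return out


def read_metadata_table(path: str | Path, traits: Sequence[str] | None = None) -> list[SampleMetadata]:
    """Read the sample-metadata table (columns sample_id, trait, extra covariates)."""
    df = _read_table(path)
    missing = [c for c in ("sample_id", "trait") if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise TableFormatError(f"{path}: duplicate sample_id {dup!r}")
    extra = [c for c in df.columns if c not in ("sample_id", "trait")]
    out = []
    for _, row in df.iterrows():
        if traits is not None and row["trait"] not in traits:
            raise TableFormatError(
                f"{path}: sample {row['sample_id']} has trait {row['trait']!r} outside {list(traits)}"
            )
        out.append(
            SampleMetadata(row["sample_id"], row["trait"], {c: row[c] for c in extra})
        )
    return out


def write_metadata_table(metadata: Sequence[SampleMetadata], path: str | Path) -> None:
    pd.DataFrame(
        [{"sample_id": m.sample_id, "trait": m.trait, **dict(m.covariates)} for m in metadata]
    ).to_csv(path, sep="\t", index=False)


# -- configuration and provenance -------------------------------------------

def load_config(path: str | Path) -> dict[str, dict[str, str]]:
    """Load an INI-style ``key = value`` config with one section per module."""
    parser = configparser.ConfigParser()
    with Path(path).open() as fh:
        parser.read_file(fh)
    return {section: dict(parser.items(section)) for section in parser.sections()}


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_manifest(
    out_dir: str | Path,
    parameters: Mapping[str, object],
    inputs: Sequence[str | Path] = (),
    seed: int | None = None,
) -> Path:
    """Write a provenance manifest (parameter values, input hashes, seed) next to outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "parameters": {k: repr(v) if not isinstance(v, (int, float, str, bool, type(None))) else v
                       for k, v in parameters.items()},
        "inputs": {str(p): file_sha256(p) for p in inputs if Path(p).exists()},
        "seed": seed,
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
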