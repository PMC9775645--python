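"""Sequence parsing, window extraction and dataset construction.

Candidate phosphorylation sites are serine, threonine or tyrosine residues.
Each sample is a 33-residue peptide window (16 residues either side of the
candidate site), gap-padded with ``-`` where the window runs past a protein
terminus.  Training negatives follow the standard convention: every
non-annotated S/T/Y residue on a protein carrying at least one confirmed
positive site.  The resulting heavy class imbalance is handled by
EasyEnsemble undersampling: each balanced subset keeps the full positive set
plus an equally sized fresh random draw of negatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = AMINO_ACIDS + GAP
CENTER_RESIDUES = ("S", "T", "Y")
NONSTANDARD = set("BJOUXZ")
WINDOW_FLANK = 16
WINDOW_LEN = 2 * WINDOW_FLANK + 1
SITE_COLUMNS = ("protein_id", "position", "residue", "label")
LABELS = ("positive", "negative", "candidate")


class FastaParseError(ValueError):
    pass


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise ValidationError("empty protein id")
        if len(self.sequence) < 1:
            raise ValidationError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValidationError(
                f"protein {self.id!r}: invalid symbols {sorted(bad)}")


@dataclass(frozen=True)
class AnnotatedSite:
    protein_id: str
    position: int          # 1-based
    residue: str           # S, T or Y
    label: str             # positive / negative / candidate

    def __post_init__(self):
        if self.residue not in CENTER_RESIDUES:
            raise ValidationError(
                f"site {self.protein_id}:{self.position}: residue "
                f"{self.residue!r} is not one of {CENTER_RESIDUES}")
        if self.label not in LABELS:
            raise ValidationError(f"unknown site label {self.label!r}")
        if self.position < 1:
            raise ValidationError("positions are 1-based and must be >= 1")


@dataclass(frozen=True)
class PeptideWindow:
    residues: str
    center_residue: str
    origin: tuple[str, int]

    def __post_init__(self):
        if len(self.residues) != WINDOW_LEN:
            raise ValidationError(
                f"window length {len(self.residues)} != {WINDOW_LEN}")
        if self.residues[WINDOW_FLANK] != self.center_residue:
            raise ValidationError("window center does not match center_residue")
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise ValidationError(f"invalid window symbols {sorted(bad)}")
        # Boundary padding is always a contiguous prefix/suffix of gaps, but
        # interior gaps can occur legitimately: unknown residues (B/J/O/U/X/Z)
        # are mapped to the null symbol, so contiguity is not enforced here.


@dataclass
class SiteDataset:
    positives: list[PeptideWindow]
    negatives: list[PeptideWindow]
    residue_type: str

    def __post_init__(self):
        if self.residue_type not in CENTER_RESIDUES:
            raise ValidationError(f"residue_type must be one of {CENTER_RESIDUES}")

    def __len__(self) -> int:
        return len(self.positives) + len(self.negatives)


@dataclass
class EnsembleSplit:
    subsets: list[SiteDataset]
    k: int


def sanitize_sequence(seq: str, protein_id: str = "?") -> str:
    """Uppercase and map nonstandard residues (B/J/O/U/X/Z) to the gap symbol."""
    seq = seq.upper()
    hits = NONSTANDARD.intersection(seq)
    if hits:
        logger.warning("protein %s: nonstandard residues %s mapped to %r",
                       protein_id, sorted(hits), GAP)
        seq = "".join(GAP if ch in NONSTANDARD else ch for ch in seq)
    return seq


def read_fasta(path) -> list[ProteinRecord]:
    """Parse a FASTA file into ProteinRecords.

    Raises :class:`FastaParseError` naming the offending line for content
    before the first header, empty headers, empty sequences or duplicate ids.
    """
    header_lines: dict[int, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    current_header_line = None
    seen_residues = False
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            if current_header_line is not None and not seen_residues:
                raise FastaParseError(
                    f"line {current_header_line}: record has an empty sequence")
            if not stripped[1:].split():
                raise FastaParseError(f"line {lineno}: empty FASTA header")
            header_lines[lineno] = stripped[1:].split()[0]
            current_header_line = lineno
            seen_residues = False
        else:
            if current_header_line is None:
                raise FastaParseError(
                    f"line {lineno}: sequence data before any '>' header")
            seen_residues = True
    if current_header_line is not None and not seen_residues:
        raise FastaParseError(
            f"line {current_header_line}: record has an empty sequence")
    ids = list(header_lines.values())
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise FastaParseError(f"duplicate FASTA ids: {dupes}")
    records = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = sanitize_sequence(str(rec.seq).replace(" ", ""), rec.id)
            records.append(ProteinRecord(rec.id, seq))
    return records


def write_fasta(records: list[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_sites(path) -> list[AnnotatedSite]:
    """Read a TSV annotation table (protein_id, position, residue, label)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"annotation file missing columns {sorted(missing)}")
    return [AnnotatedSite(str(r.protein_id), int(r.position),
                          str(r.residue), str(r.label))
            for r in df.itertuples(index=False)]


def write_sites(sites: list[AnnotatedSite], path) -> None:
    pd.DataFrame([{"protein_id": s.protein_id, "position": s.position,
                   "residue": s.residue, "label": s.label}
                  for s in sites]).to_csv(path, sep="\t", index=False)


def extract_window(record: ProteinRecord, position: int,
                   flank: int = WINDOW_FLANK) -> PeptideWindow:
    """Extract the (2*flank+1)-residue window centred on a 1-based position,
    gap-padding past the protein termini."""
    seq = record.sequence
    if not 1 <= position <= len(seq):
        raise IndexError(
            f"position {position} out of bounds for protein {record.id!r} "
            f"(length {len(seq)})")
    i = position - 1
    left = max(0, i - flank)
    right = min(len(seq), i + flank + 1)
    residues = (GAP * (flank - (i - left))
                + seq[left:right]
                + GAP * (flank - (right - 1 - i)))
    return PeptideWindow(residues, seq[i], (record.id, position))


def _index(records) -> dict[str, ProteinRecord]:
    idx = {}
    for rec in records:
        if rec.id in idx:
            raise ValidationError(f"duplicate protein id {rec.id!r}")
        idx[rec.id] = rec
    return idx


def validate_sites(records, sites) -> None:
    """Check every annotation against the sequences; raise listing all
    offending sites (unknown protein, out of bounds, residue mismatch)."""
    idx = _index(records)
    bad = []
    for s in sites:
        rec = idx.get(s.protein_id)
        if rec is None:
            bad.append(f"{s.protein_id}:{s.position} unknown protein")
        elif not 1 <= s.position <= len(rec.sequence):
            bad.append(f"{s.protein_id}:{s.position} out of bounds")
        elif rec.sequence[s.position - 1] != s.residue:
            bad.append(f"{s.protein_id}:{s.position} annotated {s.residue} "
                       f"but sequence has {rec.sequence[s.position - 1]}")
    if bad:
        raise ValidationError("invalid site annotations: " + "; ".join(bad))


def build_dataset(records, positive_sites, residue_type: str) -> SiteDataset:
    """Training-set construction rule.

    Positives: windows at the annotated positive sites of *residue_type*.
    Negatives: windows at every other *residue_type* position on proteins
    that carry at least one confirmed positive site (of any residue type).
    """
    validate_sites(records, positive_sites)
    idx = _index(records)
    pos_keys = {(s.protein_id, s.position) for s in positive_sites}
    proteins_with_pos = {s.protein_id for s in positive_sites}
    positives, negatives = [], []
    for s in positive_sites:
        if s.residue == residue_type:
            positives.append(extract_window(idx[s.protein_id], s.position))
    for pid in sorted(proteins_with_pos):
        rec = idx[pid]
        for i, ch in enumerate(rec.sequence, start=1):
            if ch == residue_type and (pid, i) not in pos_keys:
                negatives.append(extract_window(rec, i))
    return SiteDataset(positives, negatives, residue_type)


def dataset_from_sites(records, sites, residue_type: str) -> SiteDataset:
    """Build a dataset from explicitly labelled positive/negative sites
    (the evaluation and synthetic-data path; no derivation rule applied)."""
    validate_sites(records, sites)
    idx = _index(records)
    positives, negatives = [], []
    for s in sites:
        if s.residue != residue_type:
            continue
        w = extract_window(idx[s.protein_id], s.position)
        (positives if s.label == "positive" else negatives).append(w)
    return SiteDataset(positives, negatives, residue_type)


def candidate_sites(record: ProteinRecord) -> list[AnnotatedSite]:
    """All S/T/Y positions of a protein, for prediction mode (no
    positivity restriction: that rule applies only to training sets)."""
    return [AnnotatedSite(record.id, i, ch, "candidate")
            for i, ch in enumerate(record.sequence, start=1)
            if ch in CENTER_RESIDUES]


def easy_ensemble_split(dataset: SiteDataset, k: int, seed: int) -> EnsembleSplit:
    """EasyEnsemble: k balanced subsets, each holding the full positive set
    and an independent without-replacement draw of negatives of equal size."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n_pos, n_neg = len(dataset.positives), len(dataset.negatives)
    if n_pos < 1:
        raise ValueError("dataset has no positives")
    if n_neg < n_pos:
        raise ValueError(f"need at least as many negatives ({n_neg}) "
                         f"as positives ({n_pos}) to undersample")
    rng = np.random.default_rng(seed)
    subsets = []
    for _ in range(k):
        take = rng.choice(n_neg, size=n_pos, replace=False)
        subsets.append(SiteDataset(list(dataset.positives),
                                   [dataset.negatives[i] for i in take],
                                   dataset.residue_type))
    return EnsembleSplit(subsets, k)


def exact_duplicate_filter(dataset: SiteDataset) -> SiteDataset:
    """Collapse windows with identical residue strings; a window labelled
    both positive and negative is kept as positive only.  (Homology
    clustering below 70% identity is expected to be done upstream with an
    external tool; this is only an exact-match de-duplication.)"""
    pos_seen: dict[str, PeptideWindow] = {}
    for w in dataset.positives:
        pos_seen.setdefault(w.residues, w)
    neg_seen: dict[str, PeptideWindow] = {}
    for w in dataset.negatives:
        if w.residues not in pos_seen:
            neg_seen.setdefault(w.residues, w)
    return SiteDataset(list(pos_seen.values()), list(neg_seen.values()),
                       dataset.residue_type)
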