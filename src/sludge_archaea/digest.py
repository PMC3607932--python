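"""In-silico terminal restriction fragment (TRF) prediction.

In T-RFLP only the fluorescently labeled terminal fragment of each amplicon is
sized, so the quantity of interest for a 16S rRNA sequence is the distance
from the 5' labeled base (the first base of the forward primer) to the first
restriction cut site.  This module predicts that length for single sequences,
for clone sequences that start downstream of the primer (via a reference
offset), and for whole sequence collections.

Conventions
-----------
* The label origin is the first base of the forward primer; the fluorophore
  sits on the primer 5' end.
* TRF length counts the labeled-strand bases retained 5' of the cut, i.e.
  ``site_position + cut_offset - label_origin`` for the leftmost recognition
  site at or after the origin.  With blunt cutters AluI (AG^CT) and RsaI
  (GT^AC) this equals the fragment size as called on a capillary gel.
* Fragments outside the sizing window 50-1020 bases are flagged OUT_OF_RANGE
  (the raw length is retained); sequences with no site are ND.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values

logger = logging.getLogger(__name__)

#: Sizing window of the capillary electrophoresis run, in bases.
SIZE_MIN = 50
SIZE_MAX = 1020

#: Minimum exact-matching leading bases required to place a clone on the
#: reference when the mapped region is ambiguous.
MIN_MAPPING_PREFIX = 20


@dataclass(frozen=True)
class PrimerSpec:
    """A PCR primer, possibly with IUPAC degenerate positions."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("primer sequence must be nonempty")
        bad = set(self.sequence.upper()) - set(ambiguous_dna_values)
        if bad:
            raise ValueError(f"non-IUPAC characters in primer: {sorted(bad)}")


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: recognition site and cut offset on the labeled strand."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut_offset must lie within the recognition site")


#: The two enzymes of the fingerprinting protocol, both blunt 4-cutters.
ALUI = EnzymeSpec("AluI", "AGCT", 2)
RSAI = EnzymeSpec("RsaI", "GTAC", 2)

#: Archaea-specific forward primer; its first base is the label origin.
ARCH18F = PrimerSpec("Arch18F", "TTCCGGTTGATCCYGCC")
#: Archaea-specific reverse primer (not labeled; kept for completeness).
ARCH959R = PrimerSpec("Arch959R", "YCCGGCGTTGAMTCCAAT")


class DigestStatus(Enum):
    OK = "ok"
    ND = "nd"  # no recognition site downstream of the label origin
    OUT_OF_RANGE = "out_of_range"  # cut exists but fragment outside 50-1020


@dataclass(frozen=True)
class TRFPrediction:
    """Predicted terminal-fragment outcome for one sequence x one enzyme."""

    status: DigestStatus
    length: Optional[int] = None  # raw length, also retained when OUT_OF_RANGE

    @property
    def in_window(self) -> bool:
        return self.status is DigestStatus.OK


@dataclass
class SequenceRecord:
    """One 16S rRNA gene sequence with identifier and optional taxon label."""

    seq_id: str
    sequence: str
    taxon: Optional[str] = None


@dataclass
class DigestRecord:
    """Predicted TRF entries for one sequence, keyed by enzyme name."""

    seq_id: str
    entries: dict[str, TRFPrediction] = field(default_factory=dict)
    taxon: Optional[str] = None


class MappingError(ValueError):
    """Raised when a clone's leading bases cannot be placed on the reference."""


def _iupac_sets(primer: str) -> list[frozenset[str]]:
    return [frozenset(ambiguous_dna_values[c]) for c in primer.upper()]


def match_primer(sequence: str, primer: PrimerSpec) -> Optional[int]:
    """Leftmost position where the primer matches, or None.

    A primer character matches a sequence character when the character belongs
    to the primer position's IUPAC set; an N in the *sequence* matches nothing.
    """
    seq = sequence.upper()
    sets = _iupac_sets(primer.sequence)
    k = len(sets)
    for start in range(len(seq) - k + 1):
        if all(seq[start + j] in sets[j] for j in range(k)):
            return start
    return None


def _classify(length: int) -> TRFPrediction:
    if SIZE_MIN <= length <= SIZE_MAX:
        return TRFPrediction(DigestStatus.OK, length)
    return TRFPrediction(DigestStatus.OUT_OF_RANGE, length)


def predict_trf(sequence: str, enzyme: EnzymeSpec, label_origin: int = 0) -> TRFPrediction:
    """Predict the labeled terminal fragment of ``sequence`` for ``enzyme``.

    The length is the number of labeled-strand bases retained 5' of the first
    cut at or after ``label_origin``.
    """
    if not 0 <= label_origin <= len(sequence):
        raise ValueError("label_origin outside sequence")
    pos = sequence.upper().find(enzyme.recognition.upper(), label_origin)
    if pos < 0:
        return TRFPrediction(DigestStatus.ND)
    return _classify(pos + enzyme.cut_offset - label_origin)


def predict_trf_offset(
    clone: SequenceRecord,
    reference: SequenceRecord,
    enzyme: EnzymeSpec,
    primer: PrimerSpec = ARCH18F,
) -> TRFPrediction:
    """Predict a clone's TRF when the clone starts downstream of the primer.

    Partial clones that begin 50-100 bases past the primer are placed on a
    full-length reference sequence by exact prefix matching (no indels assumed
    between the primer and the clone start).  The TRF is the reference offset
    of the clone's first base plus the cut position within the clone.  If the
    reference carries a recognition site between the label origin and the
    clone start the true terminal fragment ends upstream of the clone and the
    TRF cannot be predicted (ND).
    """
    ref_seq = reference.sequence.upper()
    origin = match_primer(ref_seq, primer)
    if origin is None:
        raise MappingError(f"reference {reference.seq_id!r} lacks the primer site")
    clone_seq = clone.sequence.upper()
    prefix_len = min(MIN_MAPPING_PREFIX, len(clone_seq))
    prefix = clone_seq[:prefix_len]
    hit = ref_seq.find(prefix, origin)
    if hit < 0:
        raise MappingError(
            f"leading {prefix_len} bases of {clone.seq_id!r} not found in reference"
        )
    if ref_seq.find(prefix, hit + 1) >= 0:
        raise MappingError(f"leading bases of {clone.seq_id!r} map ambiguously")
    offset = hit - origin
    if offset == 0:
        return predict_trf(clone_seq, enzyme)
    # An upstream site on the reference means the labeled fragment ends before
    # the clone even starts: no prediction possible from the clone sequence.
    upstream = ref_seq.find(enzyme.recognition.upper(), origin, hit)
    if 0 <= upstream:
        return TRFPrediction(DigestStatus.ND)
    site = clone_seq.find(enzyme.recognition.upper())
    if site < 0:
        return TRFPrediction(DigestStatus.ND)
    return _classify(offset + site + enzyme.cut_offset)


def digest_database(
    sequences: Iterable[SequenceRecord],
    enzymes: Sequence[EnzymeSpec] = (ALUI, RSAI),
    primer: PrimerSpec = ARCH18F,
    label_origins: Optional[Mapping[str, int]] = None,
) -> tuple[list[DigestRecord], int]:
    """Digest a sequence collection with every enzyme.

    Each sequence's label origin is located with the forward primer unless an
    explicit origin is supplied via ``label_origins``.  Sequences lacking both
    are skipped with a warning; the skip count is returned alongside the
    records.
    """
    records: list[DigestRecord] = []
    skipped = 0
    for rec in sequences:
        if label_origins is not None and rec.seq_id in label_origins:
            origin = label_origins[rec.seq_id]
        else:
            origin = match_primer(rec.sequence, primer)
        if origin is None:
            logger.warning("sequence %s has no primer site; skipped", rec.seq_id)
            skipped += 1
            continue
        entries = {
            enz.name: predict_trf(rec.sequence, enz, label_origin=origin)
            for enz in enzymes
        }
        records.append(DigestRecord(rec.seq_id, entries, taxon=rec.taxon))
    return records, skipped


def read_fasta(path) -> list[SequenceRecord]:
    """Read sequences from FASTA; the description after the id becomes the taxon."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id):].strip() or None
        out.append(SequenceRecord(rec.id, str(rec.seq), taxon=desc))
    return out


def write_digest_table(records: Sequence[DigestRecord], path) -> None:
    """Write a digest table as CSV: seq_id,enzyme,status,length_bases."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["seq_id", "enzyme", "status", "length_bases"])
        for rec in records:
            for enzyme, pred in sorted(rec.entries.items()):
                writer.writerow(
                    [rec.seq_id, enzyme, pred.status.value,
                     "" if pred.length is None else pred.length]
                )
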