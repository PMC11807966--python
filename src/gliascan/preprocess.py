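"""Read preprocessing: quality trimming, pair merging, demultiplexing and
reduction of merged amplicons to the coding core.

The stages mirror a standard amplicon workflow (sliding-window quality
trimming, overlap-based pair merging, barcode demultiplexing, primer and
signal-peptide removal) and keep a strict read-fate account: every input
pair ends up in exactly one of the fate categories, so the run log always
sums to the input size.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .layout import (
    BARCODE_LENGTH,
    DEFAULT_LENGTH_BOUNDS,
    FORWARD_PRIMER,
    REV_TAIL_LENGTH,
    REVERSE_PRIMER,
    SIGNAL_REST_NT_LENGTH,
    hamming,
    iupac_mismatches,
    reverse_complement,
)

# Reverse-complement of the reverse primer: the pattern terminating a merged
# amplicon on the forward strand.
REVERSE_TAIL_PATTERN = reverse_complement(REVERSE_PRIMER)


@dataclass
class Read:
    """A FASTQ record: sequence plus Phred quality scores."""

    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and quality lengths differ")


@dataclass
class MergedCDS:
    """A demultiplexed, primer/signal-stripped coding sequence."""

    line_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def quality_trim(
    read: Read, window_size: int = 4, mean_quality_threshold: float = 15.0, min_length: int = 36
) -> Read | None:
    """Sliding-window 3' quality trimming.

    The read is truncated at the start of the first window whose mean
    quality falls below the threshold; reads shorter than ``min_length``
    afterwards are discarded (returned as None).
    """
    quals = read.qualities
    n = len(quals)
    cut = n
    for start in range(0, n - window_size + 1):
        window = quals[start : start + window_size]
        if sum(window) / window_size < mean_quality_threshold:
            cut = start
            break
    if cut < min_length:
        return None
    if cut == n:
        return read
    return Read(read.sequence[:cut], quals[:cut])


def merge_pair(
    r1: Read,
    r2: Read,
    min_overlap: int = 10,
    max_mismatch_fraction: float = 0.25,
) -> Read | None:
    """Merge a read pair by its best 3' overlap; None when none qualifies.

    ``r2`` is given in sequencing orientation and is reverse-complemented
    internally.  Among overlaps meeting the minimum length and the mismatch
    cap, the one with the best alignment score (matches − 2·mismatches)
    wins, ties broken toward the longer overlap.  A plain identity maximum
    would let a short error-free overlap inside a sequence repeat (the
    33-mer region is 21 nt periodic, glutamine runs are 3 nt periodic)
    beat the true overlap as soon as one error lands in it; the score makes
    that require implausibly many errors.  Disagreeing positions take the
    higher-quality base (ties favour R1).
    """
    b_seq = reverse_complement(r2.sequence)
    b_qual = r2.qualities[::-1]
    a_seq, a_qual = r1.sequence, r1.qualities
    n1, n2 = len(a_seq), len(b_seq)
    max_o = min(n1, n2)
    if max_o < min_overlap:
        return None

    best: tuple[int, int] | None = None  # (overlap, mismatches)
    best_score = -1
    # cheap lower bound: the longest perfect overlap (score = length)
    for o in range(max_o, min_overlap - 1, -1):
        if a_seq[n1 - o :] == b_seq[:o]:
            best, best_score = (o, 0), o
            break
    a_arr = np.frombuffer(a_seq.encode(), dtype=np.uint8)
    b_arr = np.frombuffer(b_seq.encode(), dtype=np.uint8)
    for o in range(max_o, min_overlap - 1, -1):
        if o <= best_score:  # even a perfect overlap of length o cannot win
            break
        mm = int(np.count_nonzero(a_arr[n1 - o :] != b_arr[:o]))
        if mm > int(o * max_mismatch_fraction):
            continue
        score = o - 2 * mm
        if score > best_score:
            best_score = score
            best = (o, mm)
    if best is None:
        return None

    o, mm = best
    if mm == 0:
        return Read(a_seq + b_seq[o:], a_qual + b_qual[o:])
    ov_seq = []
    ov_qual = []
    for j in range(o):
        ai = n1 - o + j
        if a_seq[ai] == b_seq[j] or a_qual[ai] >= b_qual[j]:
            ov_seq.append(a_seq[ai])
        else:
            ov_seq.append(b_seq[j])
        ov_qual.append(max(a_qual[ai], b_qual[j]))
    return Read(
        a_seq[: n1 - o] + "".join(ov_seq) + b_seq[o:],
        a_qual[: n1 - o] + ov_qual + b_qual[o:],
    )


def validate_barcode_table(barcodes: Mapping[str, str], max_barcode_mismatch: int = 0) -> None:
    """Hard-fail on barcode tables that cannot be demultiplexed uniquely."""
    items = list(barcodes.items())
    for _, bc in items:
        if len(bc) != BARCODE_LENGTH:
            raise ValueError(f"barcode {bc!r} is not {BARCODE_LENGTH} nt")
        if set(bc) - set("ACGT"):
            raise ValueError(f"barcode {bc!r} contains non-ACGT characters")
    if len({bc for _, bc in items}) != len(items):
        raise ValueError("duplicate barcodes in table")
    if max_barcode_mismatch >= 1:
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                d = hamming(items[i][1], items[j][1])
                if d < 2:
                    raise ValueError(
                        f"barcodes {items[i][0]} and {items[j][0]} are only "
                        f"{d} mismatches apart; ambiguous at tolerance "
                        f"{max_barcode_mismatch}"
                    )


def assign_barcode(
    sequence: str, barcodes: Mapping[str, str], max_barcode_mismatch: int = 0
) -> str | None:
    """Line id whose barcode uniquely matches the sequence prefix, else None."""
    prefix = sequence[:BARCODE_LENGTH]
    if len(prefix) < BARCODE_LENGTH:
        return None
    hits = [
        line
        for line, bc in barcodes.items()
        if hamming(bc, prefix, cap=max_barcode_mismatch) <= max_barcode_mismatch
    ]
    if len(hits) == 1:
        return hits[0]
    return None


def demultiplex(
    sequences: Iterable[str],
    barcodes: Mapping[str, str],
    max_barcode_mismatch: int = 0,
) -> tuple[dict[str, list[str]], list[str]]:
    """Split merged sequences by barcode prefix; returns (per-line, unassigned)."""
    validate_barcode_table(barcodes, max_barcode_mismatch)
    assigned: dict[str, list[str]] = {line: [] for line in barcodes}
    unassigned: list[str] = []
    for seq in sequences:
        line = assign_barcode(seq, barcodes, max_barcode_mismatch)
        if line is None:
            unassigned.append(seq)
        else:
            assigned[line].append(seq)
    return assigned, unassigned


def _find_pattern(seq: str, pattern: str, max_mismatch: int, expected: int | None) -> int | None:
    """Position of an IUPAC pattern, trying the expected offset first."""
    m = len(pattern)
    if expected is not None and 0 <= expected <= len(seq) - m:
        if iupac_mismatches(pattern, seq[expected : expected + m], cap=max_mismatch) <= max_mismatch:
            return expected
    best_pos, best_mm = None, max_mismatch + 1
    for pos in range(len(seq) - m + 1):
        mm = iupac_mismatches(pattern, seq[pos : pos + m], cap=best_mm - 1)
        if mm < best_mm:
            best_pos, best_mm = pos, mm
            if mm == 0:
                break
    return best_pos if best_mm <= max_mismatch else None


def strip_to_cds(
    sequence: str,
    line_id: str = "",
    *,
    barcode_length: int = BARCODE_LENGTH,
    signal_offset: int = SIGNAL_REST_NT_LENGTH,
    max_primer_mismatch: int = 1,
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
) -> tuple[MergedCDS | None, str]:
    """Excise barcode, primers and signal-peptide prefix from a merged read.

    Returns ``(cds, "ok")`` or ``(None, reason)`` with reason in
    {"no_forward_primer", "no_reverse_primer", "length", "non_acgt"}.
    ``signal_offset`` may be 0 for amplicons whose forward primer abuts the
    region of interest.
    """
    fwd_pos = _find_pattern(sequence, FORWARD_PRIMER, max_primer_mismatch, barcode_length)
    if fwd_pos is None:
        return None, "no_forward_primer"
    tail_expected = len(sequence) - REV_TAIL_LENGTH
    tail_pos = _find_pattern(sequence, REVERSE_TAIL_PATTERN, max_primer_mismatch, tail_expected)
    if tail_pos is None:
        return None, "no_reverse_primer"
    start = fwd_pos + len(FORWARD_PRIMER) + signal_offset
    if start >= tail_pos:
        return None, "length"
    cds = sequence[start:tail_pos]
    lo, hi = length_bounds
    if not lo <= len(cds) <= hi:
        return None, "length"
    if set(cds) - set("ACGT"):
        return None, "non_acgt"
    return MergedCDS(line_id, cds), "ok"


@dataclass
class PreprocessLog:
    """Read-fate accounting for one preprocessing run."""

    input_pairs: int = 0
    trim_discarded: int = 0
    merge_failed: int = 0
    unassigned: int = 0
    strip_rejected: int = 0
    retained: int = 0
    strip_reasons: Counter = field(default_factory=Counter)

    def conserved(self) -> bool:
        return (
            self.trim_discarded
            + self.merge_failed
            + self.unassigned
            + self.strip_rejected
            + self.retained
            == self.input_pairs
        )

    def as_dict(self) -> dict[str, int]:
        d = {
            "input_pairs": self.input_pairs,
            "trim_discarded": self.trim_discarded,
            "merge_failed": self.merge_failed,
            "unassigned": self.unassigned,
            "strip_rejected": self.strip_rejected,
            "retained": self.retained,
        }
        d.update({f"strip_{k}": v for k, v in sorted(self.strip_reasons.items())})
        return d


def _open_read(path: str | Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[tuple[Read, Read]]:
    """Iterate synchronized read pairs from two FASTQ files."""
    with _open_read(r1_path) as f1, _open_read(r2_path) as f2:
        it1 = SeqIO.parse(f1, "fastq")
        it2 = SeqIO.parse(f2, "fastq")
        for rec1, rec2 in zip(it1, it2, strict=True):
            yield (
                Read(str(rec1.seq), rec1.letter_annotations["phred_quality"]),
                Read(str(rec2.seq), rec2.letter_annotations["phred_quality"]),
            )


def load_barcode_table(path: str | Path) -> dict[str, str]:
    """Barcode TSV (columns line_id, barcode) -> mapping."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["line_id"], df["barcode"].str.upper()))


def run_preprocess(
    r1_path: str | Path,
    r2_path: str | Path,
    barcodes: Mapping[str, str],
    *,
    window_size: int = 4,
    mean_quality_threshold: float = 15.0,
    min_length: int = 36,
    min_overlap: int = 10,
    max_mismatch_fraction: float = 0.25,
    max_barcode_mismatch: int = 0,
    signal_offset: int = SIGNAL_REST_NT_LENGTH,
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, Counter], PreprocessLog]:
    """Full preprocessing: FASTQ pair files -> per-line CDS multisets.

    Identical (post-trim) read pairs are collapsed before merging, which
    leaves results unchanged but makes low-error runs fast.  Returns a
    mapping line_id -> Counter(cds -> copies) and the fate log; optionally
    writes per-line FASTA files and a run-log TSV to ``out_dir``.
    """
    validate_barcode_table(barcodes, max_barcode_mismatch)
    log = PreprocessLog()
    pair_counts: Counter[tuple[str, str, tuple[int, ...], tuple[int, ...]]] = Counter()
    for r1, r2 in read_pairs(r1_path, r2_path):
        log.input_pairs += 1
        t1 = quality_trim(r1, window_size, mean_quality_threshold, min_length)
        t2 = quality_trim(r2, window_size, mean_quality_threshold, min_length)
        if t1 is None or t2 is None:
            log.trim_discarded += 1
            continue
        pair_counts[
            (t1.sequence, t2.sequence, tuple(t1.qualities), tuple(t2.qualities))
        ] += 1

    per_line: dict[str, Counter] = {line: Counter() for line in barcodes}
    for (s1, s2, q1, q2), copies in pair_counts.items():
        merged = merge_pair(
            Read(s1, list(q1)), Read(s2, list(q2)), min_overlap, max_mismatch_fraction
        )
        if merged is None:
            log.merge_failed += copies
            continue
        line = assign_barcode(merged.sequence, barcodes, max_barcode_mismatch)
        if line is None:
            log.unassigned += copies
            continue
        cds, reason = strip_to_cds(
            merged.sequence,
            line,
            signal_offset=signal_offset,
            length_bounds=length_bounds,
        )
        if cds is None:
            log.strip_rejected += copies
            log.strip_reasons[reason] += copies
            continue
        per_line[line][cds.sequence] += copies
        log.retained += copies

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for line, counter in per_line.items():
            with open(out / f"{line}.cds.fasta", "w") as fh:
                i = 0
                for seq, copies in counter.items():
                    for _ in range(copies):
                        fh.write(f">{line}|cds{i}\n{seq}\n")
                        i += 1
        import pandas as pd

        pd.DataFrame([log.as_dict()]).to_csv(out / "preprocess_log.tsv", sep="\t", index=False)
    return per_line, log
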