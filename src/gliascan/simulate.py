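"""Synthetic alpha-gliadin amplicon generator with known epitope content.

Templates emulate the structure of the sequenced amplicon: an in-frame
coding region for the N-terminal repetitive domain, flanked by the
degenerate gene-specific primers, carrying a per-line 8 nt barcode, and
expressed at log-normal copy numbers.  Each template records its ground
truth: the epitope occurrences a brute-force scan finds in its protein
core.  Paired 250 bp reads are emitted with i.i.d. substitution errors, so
the full downstream pipeline can be validated by parameter recovery.

The epitope-bearing cores are built by embedding catalogue peptides in a
spacer scaffold whose residues (ADEGNSTV) are deliberately scarce in the
proline/glutamine-rich epitope vocabulary, so spurious catalogue matches
are rare; the builder re-scans every core and records what was actually
realized rather than what was requested.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalogue import THIRTY_THREE_MER, EpitopeRecord, scannable
from .layout import (
    BARCODE_LENGTH,
    CORE_OFFSET,
    FORWARD_PRIMER,
    REV_TAIL_LENGTH,
    REVERSE_PRIMER,
    SIGNAL_REST_AA,
    realize_iupac,
    reverse_complement,
)

SPACER_ALPHABET = "ADEGNSTV"
MIN_CORE_AA = 64   # 192 nt
MAX_CORE_AA = 144  # 432 nt (observed upper bound for real coding cores)

# Default geometric cap for generated cores.  With 250 nt reads the pair
# must overlap after barcode, primers and signal remainder, and the true
# overlap must extend beyond the longest sequence repeat or merging is
# inherently ambiguous: the 33-mer region is 21 nt periodic over 63 nt, so
# a short overlap lying inside it merges equally well at a ±1-repeat shift.
# A core of <= 112 aa (336 nt) leaves >= 76 nt of true overlap, which no
# repeat in the amplicon can span.
MERGEABLE_CORE_AA = 112

# Eight 8-mers with pairwise Hamming distance >= 4: rotations of ACGT and
# AGCT doubled, so single-substitution demultiplexing stays unambiguous.
DEFAULT_BARCODES = (
    "ACGTACGT",
    "CGTACGTA",
    "GTACGTAC",
    "TACGTACG",
    "AGCTAGCT",
    "GCTAGCTA",
    "CTAGCTAG",
    "TAGCTAGC",
)


class ImpossiblePlanError(ValueError):
    """Raised when a requested epitope plan cannot fit in one amplicon."""


def load_codon_table() -> dict[str, str]:
    """Residue -> codon map (most frequent wheat codon per residue)."""
    path = resources.files("gliascan").joinpath("data/wheat_codons.tsv")
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["residue"], df["codon"]))


_CODONS = load_codon_table()


def back_translate(protein: str) -> str:
    """Deterministic back-translation using the fixed codon table."""
    try:
        return "".join(_CODONS[aa] for aa in protein)
    except KeyError as exc:
        raise ValueError(f"cannot back-translate residue {exc}") from exc


def naive_scan(
    protein: str, records: Sequence[EpitopeRecord], max_mismatch: int = 1
) -> dict[str, int]:
    """Brute-force epitope occurrence counts over every window.

    Every (position, epitope-length) window is compared against every
    scannable record; a window is attributed to the minimum-mismatch record
    (exact matches therefore always win; remaining ties go to catalogue
    order).  Used to record template ground truth; the analysis-side scanner
    in :mod:`gliascan.quantify` is implemented independently.
    """
    recs = scannable(records)
    lengths = sorted({len(r.peptide) for r in recs})
    counts: dict[str, int] = {}
    for length in lengths:
        of_len = [r for r in recs if len(r.peptide) == length]
        for start in range(len(protein) - length + 1):
            window = protein[start : start + length]
            best_rec = None
            best_mm = max_mismatch + 1
            for rec in of_len:
                mm = 0
                for a, b in zip(window, rec.peptide):
                    if a != b:
                        mm += 1
                        if mm >= best_mm:
                            break
                if mm < best_mm:
                    best_mm = mm
                    best_rec = rec
                    if mm == 0:
                        break
            if best_rec is not None and best_mm <= max_mismatch:
                counts[best_rec.name] = counts.get(best_rec.name, 0) + 1
    return counts


@dataclass
class AmpliconTemplate:
    """A ground-truth amplicon: one alpha-gliadin transcript variant."""

    line_id: str
    barcode: str
    protein_core: str
    cds: str  # full amplicon: barcode + fwd primer + signal rest + core + rev tail
    abundance: int
    is_pseudogene: bool
    truth_epitopes: dict[str, int] = field(default_factory=dict)

    @property
    def core_cds(self) -> str:
        """The in-frame coding core between the layout landmarks."""
        return self.cds[CORE_OFFSET : len(self.cds) - REV_TAIL_LENGTH]


@dataclass
class SimConfig:
    """Desk-scale simulation parameters (seed fully determines output)."""

    n_lines: int = 8
    templates_per_line: int = 50
    abundance_mean: float = 100.0
    abundance_sigma: float = 0.4
    min_abundance: int = 20
    read_length: int = 250
    error_rate: float = 0.001
    pseudogene_fraction: float = 0.05
    truth_max_mismatch: int = 1
    seed: int = 0
    quality_char: str = "I"  # Phred+33 Q40

    def __post_init__(self) -> None:
        for name in ("error_rate", "pseudogene_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be within [0, 1], got {v}")
        if self.read_length <= BARCODE_LENGTH + len(FORWARD_PRIMER):
            raise ValueError("read_length shorter than barcode + forward primer")


def _spacer(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(len(SPACER_ALPHABET), size=length)
    return "".join(SPACER_ALPHABET[i] for i in idx)


def _resolve_plan(
    plan: Sequence[tuple[str, int]], records: Sequence[EpitopeRecord]
) -> list[str]:
    """Expand a plan into the peptide strings to embed."""
    by_name = {r.name: r for r in records}
    peptides: list[str] = []
    for name, count in plan:
        if count < 1:
            raise ValueError(f"plan count for {name!r} must be positive")
        if name == "33mer":
            pep = THIRTY_THREE_MER
        else:
            rec = by_name.get(name)
            if rec is None:
                raise KeyError(f"epitope {name!r} not in catalogue")
            if rec.scan_excluded:
                raise ValueError(f"epitope {name!r} is excluded from scanning")
            pep = rec.peptide
        peptides.extend([pep] * count)
    return peptides


def build_template(
    line_id: str,
    barcode: str,
    plan: Sequence[tuple[str, int]],
    rng: np.random.Generator,
    records: Sequence[EpitopeRecord],
    *,
    abundance: int = 1,
    target_core_aa: int | None = None,
    is_pseudogene: bool = False,
    truth_max_mismatch: int = 1,
    max_attempts: int = 5,
    max_core_aa: int = MERGEABLE_CORE_AA,
) -> AmpliconTemplate:
    """Embed the planned epitopes in a scaffold and realize the amplicon.

    The realized truth (a re-scan of the built core) is recorded on the
    template; it is at least the requested plan and may exceed it when
    embeddings overlap-compose (e.g. the 33-mer creates six epitopes).
    """
    peptides = _resolve_plan(plan, records)
    min_content = sum(len(p) for p in peptides) + 3 * (len(peptides) + 1)
    if min_content > max_core_aa:
        culprits = " and ".join(f"{n}×{c}" for n, c in plan)
        raise ImpossiblePlanError(
            f"plan does not fit in {max_core_aa} residues: {culprits}"
        )
    if target_core_aa is None:
        lo = max(70, min_content)
        target_core_aa = int(rng.integers(lo, max(lo + 1, 111)))
    target_core_aa = min(max(target_core_aa, min_content, MIN_CORE_AA), max_core_aa)

    planned = naive_scan("#".join(peptides), records, truth_max_mismatch) if peptides else {}

    core = ""
    for attempt in range(max_attempts):
        order = list(peptides)
        if len(order) > 1:
            rng.shuffle(order)
        parts = []
        for pep in order:
            parts.append(_spacer(rng, int(rng.integers(3, 8))))
            parts.append(pep)
        parts.append(_spacer(rng, int(rng.integers(3, 8))))
        core = "".join(parts)
        if len(core) > max_core_aa:
            # random spacers overshot the geometric cap; rebuild minimal
            parts = []
            for pep in order:
                parts.append(_spacer(rng, 3))
                parts.append(pep)
            parts.append(_spacer(rng, 3))
            core = "".join(parts)
        if len(core) < target_core_aa:
            core += _spacer(rng, target_core_aa - len(core))
        realized = naive_scan(core, records, truth_max_mismatch)
        # accept only scaffolds that add nothing beyond what the embedded
        # peptides themselves imply (junction windows can otherwise sit at
        # the mismatch tolerance and create fragile truth); retry otherwise
        if realized == planned:
            break

    core_nt = back_translate(core)
    protein_core = core
    if is_pseudogene:
        # knock a spacer codon out to an internal stop, as in the
        # pseudogene fraction of the real alpha-gliadin family
        spacer_positions = [
            i for i, aa in enumerate(core) if aa in SPACER_ALPHABET
        ]
        pos = int(spacer_positions[rng.integers(len(spacer_positions))])
        core_nt = core_nt[: 3 * pos] + "TAA" + core_nt[3 * pos + 3 :]
        protein_core = core[:pos] + "*" + core[pos + 1 :]

    amplicon = (
        barcode
        + realize_iupac(FORWARD_PRIMER, rng)
        + back_translate(SIGNAL_REST_AA)
        + core_nt
        + reverse_complement(realize_iupac(REVERSE_PRIMER, rng))
    )
    return AmpliconTemplate(
        line_id=line_id,
        barcode=barcode,
        protein_core=protein_core,
        cds=amplicon,
        abundance=abundance,
        is_pseudogene=is_pseudogene,
        truth_epitopes=naive_scan(protein_core, records, truth_max_mismatch),
    )


def margin_safe_records(records: Sequence[EpitopeRecord]) -> list[EpitopeRecord]:
    """Records whose embedded occurrences are all exact catalogue matches.

    A peptide can imply occurrences of other catalogue entries at exactly
    the scan tolerance (e.g. a composite long variant containing a window
    one mismatch away from a 9-mer entry).  Such boundary occurrences have
    zero mismatch margin: any sequencing error inside the window removes
    them, so recovery of their counts degrades with the error rate rather
    than with the (much rarer) double-error rate.  The default simulator
    plans embed only margin-safe peptides; boundary composites remain
    available to :func:`build_template` explicitly.
    """
    return [
        r
        for r in scannable(records)
        if naive_scan(r.peptide, records, 1) == naive_scan(r.peptide, records, 0)
    ]


def sample_epitope_plan(
    rng: np.random.Generator,
    records: Sequence[EpitopeRecord],
    candidates: Sequence[EpitopeRecord] | None = None,
) -> list[tuple[str, int]]:
    """Default per-template plan: occasional 33-mer plus a few epitopes.

    Canonical epitopes are drawn four times as often as variants, so the
    high-abundance rows of the resulting count matrices are the canonical
    ones, as in real alpha-gliadin repertoires.
    """
    recs = list(candidates) if candidates is not None else margin_safe_records(records)
    weights = np.array([4.0 if r.canonical else 1.0 for r in recs])
    weights /= weights.sum()
    plan: dict[str, int] = {}
    budget = MERGEABLE_CORE_AA - 4  # leaves room for the flanking spacers
    if rng.random() < 0.25:
        plan["33mer"] = 1
        budget -= len(THIRTY_THREE_MER) + 3
    n_extra = 1 + int(rng.poisson(1.5))
    for _ in range(n_extra):
        rec = recs[int(rng.choice(len(recs), p=weights))]
        cost = len(rec.peptide) + 3
        if cost > budget:
            break
        plan[rec.name] = plan.get(rec.name, 0) + 1
        budget -= cost
    return sorted(plan.items())


def _draw_abundance(rng: np.random.Generator, config: SimConfig) -> int:
    mu = np.log(config.abundance_mean) - config.abundance_sigma**2 / 2
    ab = int(round(rng.lognormal(mu, config.abundance_sigma)))
    return max(ab, config.min_abundance, 1)


def build_line_templates(
    config: SimConfig, records: Sequence[EpitopeRecord], rng: np.random.Generator
) -> list[AmpliconTemplate]:
    """All templates for one simulated run."""
    if config.n_lines > len(DEFAULT_BARCODES):
        raise ValueError(f"at most {len(DEFAULT_BARCODES)} lines supported by default barcodes")
    templates: list[AmpliconTemplate] = []
    candidates = margin_safe_records(records)
    for li in range(config.n_lines):
        line_id = f"line{li + 1}"
        barcode = DEFAULT_BARCODES[li]
        for _ in range(config.templates_per_line):
            plan = sample_epitope_plan(rng, records, candidates)
            is_pseudo = bool(rng.random() < config.pseudogene_fraction)
            templates.append(
                build_template(
                    line_id,
                    barcode,
                    plan,
                    rng,
                    records,
                    abundance=_draw_abundance(rng, config),
                    is_pseudogene=is_pseudo,
                    truth_max_mismatch=config.truth_max_mismatch,
                )
            )
    return templates


def _open_write(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


_BASES = "ACGT"
_OTHER = {b: _BASES.replace(b, "") for b in _BASES}


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0.0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    for pos in positions:
        alts = _OTHER.get(chars[pos], _BASES)
        chars[pos] = alts[rng.integers(len(alts))]
    return "".join(chars)


def emit_reads(
    templates: Sequence[AmpliconTemplate],
    config: SimConfig,
    r1_path: str | Path,
    r2_path: str | Path,
) -> int:
    """Write paired FASTQ files; returns the number of read pairs emitted.

    Each template yields ``abundance`` pairs: R1 from the barcoded 5' end,
    R2 the reverse complement of the 3' end, both ``read_length`` long (the
    amplicon always exceeds the read length, so pairs merge by overlap).
    """
    rng = np.random.default_rng(config.seed + 1)
    n_pairs = 0
    with _open_write(Path(r1_path)) as f1, _open_write(Path(r2_path)) as f2:
        for ti, tpl in enumerate(templates):
            fwd = tpl.cds[: config.read_length]
            rev = reverse_complement(tpl.cds)[: config.read_length]
            for ci in range(tpl.abundance):
                r1 = _mutate(fwd, rng, config.error_rate)
                r2 = _mutate(rev, rng, config.error_rate)
                rid = f"{tpl.line_id}|t{ti}|c{ci}"
                f1.write(f"@{rid}/1\n{r1}\n+\n{config.quality_char * len(r1)}\n")
                f2.write(f"@{rid}/2\n{r2}\n+\n{config.quality_char * len(r2)}\n")
                n_pairs += 1
    return n_pairs


def truth_table(
    templates: Sequence[AmpliconTemplate],
) -> pd.DataFrame:
    """Abundance-weighted expected counts per line and epitope.

    Pseudogene templates are excluded: their transcripts carry internal
    stops and are discarded by the pipeline before epitope counting.
    Columns: line_id, epitope, count, depth, normalized (per million).
    """
    depths: dict[str, int] = {}
    counts: dict[tuple[str, str], int] = {}
    for tpl in templates:
        if tpl.is_pseudogene:
            continue
        depths[tpl.line_id] = depths.get(tpl.line_id, 0) + tpl.abundance
        for name, occ in tpl.truth_epitopes.items():
            key = (tpl.line_id, name)
            counts[key] = counts.get(key, 0) + occ * tpl.abundance
    rows = [
        {
            "line_id": line,
            "epitope": name,
            "count": c,
            "depth": depths[line],
            "normalized": c * 1e6 / depths[line],
        }
        for (line, name), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["line_id", "epitope", "count", "depth", "normalized"])


@dataclass
class SimResult:
    """Paths and in-memory objects from one simulated sequencing run."""

    config: SimConfig
    templates: list[AmpliconTemplate]
    r1_path: Path
    r2_path: Path
    truth_path: Path
    barcode_path: Path
    n_pairs: int

    @property
    def barcodes(self) -> dict[str, str]:
        seen: dict[str, str] = {}
        for tpl in self.templates:
            seen[tpl.line_id] = tpl.barcode
        return seen


def simulate_run(
    config: SimConfig,
    records: Sequence[EpitopeRecord],
    out_dir: str | Path,
    gzip_fastq: bool = False,
) -> SimResult:
    """Generate templates, reads, truth table and barcode table in out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    templates = build_line_templates(config, records, rng)
    suffix = ".fastq.gz" if gzip_fastq else ".fastq"
    r1 = out / f"reads_R1{suffix}"
    r2 = out / f"reads_R2{suffix}"
    n_pairs = emit_reads(templates, config, r1, r2)
    truth = out / "truth.tsv"
    truth_table(templates).to_csv(truth, sep="\t", index=False)
    bc_path = out / "barcodes.tsv"
    seen: dict[str, str] = {}
    for tpl in templates:
        seen.setdefault(tpl.line_id, tpl.barcode)
    pd.DataFrame(
        {"line_id": list(seen), "barcode": [seen[k] for k in seen]}
    ).to_csv(bc_path, sep="\t", index=False)
    return SimResult(config, templates, r1, r2, truth, bc_path, n_pairs)
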