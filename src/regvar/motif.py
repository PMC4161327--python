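"""Allele-specific transcription-factor motif prediction.

Predicts whether a SNP allele creates or disrupts a binding motif — the
in-silico counterpart of an EMSA probe comparison. A position frequency
matrix (PFM, JASPAR text format) is converted into a log₂-odds position
weight matrix and scanned over both strands of each allele's probe
sequence; the call is made on the best-hit relative scores.

Conventions:

* alphabet order A, C, G, T throughout;
* log-odds: ``log2((count + pc·bg) / (colsum + pc) / bg)`` with pseudocount
  ``pc`` distributed by the background ``bg`` (uniform by default);
* ``rel_score = (score − min_score) / (max_score − min_score)`` so the
  consensus scores exactly 1 and the anti-consensus exactly 0;
* best-hit ties broken toward the + strand, then the smallest offset.

Also houses two small sequence utilities used around the motif analysis:
allele probe-pair construction (the 21-bp EMSA oligo design) and an exact
in-silico PCR amplicon check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_BASE_INDEX[b] for b in seq), dtype=np.int64, count=len(seq))
    except KeyError as exc:
        raise ValueError(
            f"sequence contains non-ACGT character {exc.args[0]!r}; "
            "ambiguity codes are not allowed (probes are fully specified)"
        ) from None


@dataclass
class PFM:
    """Position frequency matrix: 4 × L nonnegative counts, rows A,C,G,T."""

    motif_id: str
    tf_name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x L matrix (rows A,C,G,T)")
        if self.counts.shape[1] < 1:
            raise ValueError("motif length must be >= 1")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError("every column must have a positive count sum")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        """Highest-count base per column (ties resolved in A,C,G,T order)."""
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


@dataclass
class PWMModel:
    """Log₂-odds scoring matrix derived from a PFM with background + pseudocount."""

    pfm: PFM
    background: np.ndarray
    pseudocount: float
    logodds: np.ndarray
    max_score: float
    min_score: float

    @property
    def length(self) -> int:
        return self.logodds.shape[1]

    def rel_score(self, score: float) -> float:
        span = self.max_score - self.min_score
        if span == 0.0:
            return 1.0  # uninformative matrix: every window is "the best"
        return (score - self.min_score) / span


@dataclass(frozen=True)
class MotifHit:
    """Best-scoring window: 0-based offset in the original sequence, strand, scores."""

    offset: int
    strand: str
    score: float
    rel_score: float


@dataclass(frozen=True)
class AlleleProbePair:
    """Equal-length allele probe sequences differing at exactly one offset."""

    variant_id: str
    ref_seq: str
    alt_seq: str
    snp_offset: int

    def __post_init__(self) -> None:
        if len(self.ref_seq) != len(self.alt_seq):
            raise ValueError("allele probes must have equal length")
        diffs = [i for i, (a, b) in enumerate(zip(self.ref_seq, self.alt_seq)) if a != b]
        if diffs != [self.snp_offset]:
            raise ValueError(
                f"probes must differ at exactly snp_offset={self.snp_offset}; "
                f"differ at {diffs}"
            )

    @property
    def ref_antisense(self) -> str:
        return reverse_complement(self.ref_seq)

    @property
    def alt_antisense(self) -> str:
        return reverse_complement(self.alt_seq)


@dataclass(frozen=True)
class AllelicEffect:
    """Per-allele best hits and the created/disrupted/neutral call."""

    variant_id: str
    ref_hit: MotifHit
    alt_hit: MotifHit
    delta: float
    call: str


def read_jaspar_pfm(source: str | Path) -> list[PFM]:
    """Parse JASPAR-format PFM text (path or literal text) into PFMs.

    Accepts both the bracketed dialect (``A [ 1 2 3 ]``) and bare
    whitespace-separated count rows; labeled rows may appear in any order,
    unlabeled rows are taken in A,C,G,T order.
    """
    text = source if isinstance(source, str) and "\n" in source else None
    if text is None:
        p = Path(source)
        if p.exists():
            text = p.read_text()
        else:
            text = str(source)  # single-line literal without newline? treat as text
    motifs: list[PFM] = []
    header: tuple[str, str] | None = None
    rows: list[tuple[str | None, list[float]]] = []

    def flush() -> None:
        nonlocal rows, header
        if header is None and not rows:
            return
        if header is None:
            raise ValueError("count rows found before any '>' header")
        if len(rows) != 4:
            raise ValueError(
                f"motif {header[0]}: expected 4 base rows, got {len(rows)}"
            )
        labeled = all(lbl is not None for lbl, _ in rows)
        if labeled:
            by_base = {lbl: vals for lbl, vals in rows}
            if set(by_base) != set(BASES):
                missing = sorted(set(BASES) - set(by_base))
                raise ValueError(f"motif {header[0]}: missing base row(s) {missing}")
            ordered = [by_base[b] for b in BASES]
        else:
            ordered = [vals for _, vals in rows]
        lengths = {len(v) for v in ordered}
        if len(lengths) != 1:
            raise ValueError(f"motif {header[0]}: rows of unequal length {sorted(lengths)}")
        motifs.append(PFM(motif_id=header[0], tf_name=header[1], counts=np.array(ordered)))
        rows, header = [], None

    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            parts = line[1:].split(None, 1)
            if not parts:
                raise ValueError("empty '>' header line")
            header = (parts[0], parts[1].strip() if len(parts) > 1 else parts[0])
            continue
        label: str | None = None
        body = line
        if line[0] in BASES and (len(line) == 1 or not line[1].isdigit() and line[1] not in ".-"):
            label, body = line[0], line[1:]
        body = body.replace("[", " ").replace("]", " ")
        try:
            vals = [float(x) for x in body.split()]
        except ValueError:
            raise ValueError(f"cannot parse count row: {raw!r}") from None
        rows.append((label, vals))
    flush()
    if not motifs:
        raise ValueError("no motifs found in input")
    return motifs


def load_foxa_core_pfm() -> PFM:
    """The bundled strict forkhead-core fixture (synthetic, consensus TGTTTAC).

    An authored stand-in for a database FOXA matrix, built so that the
    highly constrained center position (the one a risk allele can supply)
    dominates the score: completing it is required to reach a 0.8 relative
    score. Real JASPAR files load through :func:`read_jaspar_pfm`.
    """
    from importlib.resources import files

    text = files("regvar.data").joinpath("foxa_core_synthetic.jaspar").read_text()
    return read_jaspar_pfm(text)[0]


def pfm_to_pwm(
    pfm: PFM,
    background: Sequence[float] | None = None,
    pseudocount: float = 1.0,
) -> PWMModel:
    """Log₂-odds PWM with the pseudocount distributed by the background.

    ``logodds[b][j] = log2((counts[b][j] + pc·bg[b]) / (colsum_j + pc) / bg[b])``.
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=np.float64)
    if bg.shape != (4,):
        raise ValueError("background must have 4 entries (A,C,G,T)")
    if (bg <= 0).any():
        raise ValueError("background probabilities must all be positive")
    if abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background must sum to 1")
    if pseudocount <= 0 and (pfm.counts == 0).any():
        raise ValueError("pseudocount must be > 0 when the PFM contains zero counts")
    colsum = pfm.counts.sum(axis=0)
    probs = (pfm.counts + pseudocount * bg[:, None]) / (colsum + pseudocount)
    logodds = np.log2(probs / bg[:, None])
    return PWMModel(
        pfm=pfm,
        background=bg,
        pseudocount=float(pseudocount),
        logodds=logodds,
        max_score=float(logodds.max(axis=0).sum()),
        min_score=float(logodds.min(axis=0).sum()),
    )


def _window_scores(pwm: PWMModel, seq: str) -> np.ndarray:
    """Scores of every + strand window of ``seq`` (length n − L + 1)."""
    enc = _encode(seq)
    L = pwm.length
    n = len(seq) - L + 1
    scores = np.empty(n, dtype=np.float64)
    for o in range(n):
        scores[o] = pwm.logodds[enc[o : o + L], np.arange(L)].sum()
    return scores


def scan_all_windows(pwm: PWMModel, seq: str) -> list[MotifHit]:
    """Every (offset, strand) window hit; offsets refer to the input sequence."""
    L = pwm.length
    if len(seq) < L:
        raise ValueError(f"sequence length {len(seq)} shorter than motif length {L}")
    hits: list[MotifHit] = []
    fwd = _window_scores(pwm, seq)
    for o, s in enumerate(fwd):
        hits.append(MotifHit(offset=o, strand="+", score=float(s),
                             rel_score=float(pwm.rel_score(s))))
    rev = _window_scores(pwm, reverse_complement(seq))
    for o, s in enumerate(rev):
        orig = len(seq) - L - o
        hits.append(MotifHit(offset=orig, strand="-", score=float(s),
                             rel_score=float(pwm.rel_score(s))))
    return hits


def scan_best_hit(pwm: PWMModel, seq: str) -> MotifHit:
    """Highest-scoring window over all offsets and both strands.

    Ties are broken toward the + strand, then the smallest offset.
    """
    hits = scan_all_windows(pwm, seq)
    return max(hits, key=lambda h: (h.score, h.strand == "+", -h.offset))


def consensus_core_match(pwm: PWMModel, seq: str, rel_score_threshold: float = 0.8) -> int:
    """Count of (offset, strand) windows with rel_score ≥ threshold."""
    return sum(1 for h in scan_all_windows(pwm, seq) if h.rel_score >= rel_score_threshold)


def allelic_motif_effect(
    pwm: PWMModel,
    probes: AlleleProbePair,
    rel_score_threshold: float = 0.8,
) -> AllelicEffect:
    """Created/disrupted/neutral call from per-allele best hits.

    ``delta = score(alt best) − score(ref best)``; the call is *created*
    when only the alt allele clears the relative-score threshold,
    *disrupted* in the mirror case, *neutral* otherwise.
    """
    ref_hit = scan_best_hit(pwm, probes.ref_seq)
    alt_hit = scan_best_hit(pwm, probes.alt_seq)
    if alt_hit.rel_score >= rel_score_threshold > ref_hit.rel_score:
        call = "created"
    elif ref_hit.rel_score >= rel_score_threshold > alt_hit.rel_score:
        call = "disrupted"
    else:
        call = "neutral"
    return AllelicEffect(
        variant_id=probes.variant_id,
        ref_hit=ref_hit,
        alt_hit=alt_hit,
        delta=alt_hit.score - ref_hit.score,
        call=call,
    )


def make_allele_probes(
    reference_seq: str,
    snp_offset: int,
    ref_allele: str,
    alt_allele: str,
    variant_id: str = "variant",
) -> AlleleProbePair:
    """Build the two allele probes from a reference-allele sequence.

    ``reference_seq[snp_offset]`` must equal ``ref_allele``; the alt probe
    substitutes ``alt_allele`` at that offset. Antisense strands are
    available as reverse complements on the returned pair.
    """
    reference_seq = reference_seq.upper()
    ref_allele, alt_allele = ref_allele.upper(), alt_allele.upper()
    if ref_allele == alt_allele:
        raise ValueError("ref and alt alleles are identical")
    if not (0 <= snp_offset < len(reference_seq)):
        raise ValueError(f"snp_offset {snp_offset} outside sequence of length {len(reference_seq)}")
    if reference_seq[snp_offset] != ref_allele:
        raise ValueError(
            f"reference sequence has {reference_seq[snp_offset]!r} at offset "
            f"{snp_offset}, expected ref allele {ref_allele!r}"
        )
    alt_seq = reference_seq[:snp_offset] + alt_allele + reference_seq[snp_offset + 1 :]
    return AlleleProbePair(
        variant_id=variant_id, ref_seq=reference_seq, alt_seq=alt_seq, snp_offset=snp_offset
    )


def in_silico_amplicon(template: str, fwd_primer: str, rev_primer: str) -> list[int]:
    """Exact-match PCR product lengths on a template.

    Finds every exact occurrence of the forward primer on the + strand and
    of the reverse complement of the reverse primer downstream of it; each
    pairing yields a product length measured end-to-end, inclusive of both
    primers. No product is an empty list, not an error.
    """
    template = template.upper()
    fwd = fwd_primer.upper()
    rev = rev_primer.upper()
    if len(fwd) < 15 or len(rev) < 15:
        raise ValueError("primers must be at least 15 nt")
    rev_site = reverse_complement(rev)

    def find_all(hay: str, needle: str) -> list[int]:
        out, i = [], hay.find(needle)
        while i != -1:
            out.append(i)
            i = hay.find(needle, i + 1)
        return out

    lengths = []
    for f in find_all(template, fwd):
        for r in find_all(template, rev_site):
            end = r + len(rev_site)
            if r >= f and end - f >= max(len(fwd), len(rev)):
                lengths.append(end - f)
    return sorted(lengths)


def write_motif_report(effects: Iterable[AllelicEffect], motif_id: str, path: str | Path) -> None:
    """TSV motif report: variant, motif, per-allele scores, delta, call."""
    lines = [
        "variant_id\tmotif_id\tref_score\tref_rel_score\talt_score\talt_rel_score\tdelta\tcall"
    ]
    for e in effects:
        lines.append(
            f"{e.variant_id}\t{motif_id}\t{e.ref_hit.score:.4f}\t{e.ref_hit.rel_score:.4f}"
            f"\t{e.alt_hit.score:.4f}\t{e.alt_hit.rel_score:.4f}\t{e.delta:.4f}\t{e.call}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
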