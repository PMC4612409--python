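"""Affine-gap local alignment of bisulfite reads to converted amplicon templates.

Bisulfite treatment converts unmethylated cytosine to uracil (read as T after
PCR) while 5-methylcytosine stays C.  Rather than penalize reads for their
methylation state, the template is converted once: non-CpG C becomes T and
each CpG C becomes the wildcard Y, which matches read C or T at full match
score.  The complementary strand is represented in plus orientation with
non-CpG G → A and CpG G → wildcard R (matching A or G).  Reads are aligned to
both converted references with the Smith-Waterman local algorithm using
Gotoh's three-state affine-gap recurrence; the higher-scoring orientation is
reported (ties go to forward).

A read's maximum attainable score is match_score × read_length (a gapless
perfect full-length match), making the score fraction read-length normalized;
reads at or above the retention threshold (default 0.80) are analysed further.

Coordinates are 0-based half-open.  Traceback tie-break: prefer diagonal, then
consuming a read base (gap in template), then consuming a template base; the
first-encountered maximal cell in row-major order wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .cpg import list_cpg_sites

__all__ = [
    "ScoringScheme",
    "AmpliconTemplate",
    "AlignmentResult",
    "bisulfite_convert_template",
    "revcomp",
    "max_attainable_score",
    "align_read",
    "local_alignment_score",
    "filter_reads",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "Y": 4, "R": 5, "N": 6}
_COMPLEMENT = str.maketrans("ACGTYRN", "TGCARYN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[b] for b in seq.upper()], dtype=np.int8)
    except KeyError as e:
        raise ValueError(f"invalid sequence character {e.args[0]!r}") from None


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scores; wildcards Y (C/T) and R (A/G) score as matches."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("mismatch and gap scores must be ≤ 0")
        if self.gap_extend < self.gap_open:
            raise ValueError("gap_extend must be ≥ gap_open")

    def matrix(self) -> np.ndarray:
        """7×7 substitution matrix over A,C,G,T,Y,R,N (template on axis 1)."""
        m = np.full((7, 7), self.mismatch, dtype=np.float64)
        for i in range(4):
            m[i, i] = self.match
        for read_base in (_CODE["C"], _CODE["T"]):
            m[read_base, _CODE["Y"]] = self.match
            m[_CODE["Y"], read_base] = self.match
        for read_base in (_CODE["A"], _CODE["G"]):
            m[read_base, _CODE["R"]] = self.match
            m[_CODE["R"], read_base] = self.match
        m[_CODE["Y"], _CODE["Y"]] = self.match
        m[_CODE["R"], _CODE["R"]] = self.match
        m[_CODE["N"], :] = self.mismatch
        m[:, _CODE["N"]] = self.mismatch
        return m


def bisulfite_convert_template(
    seq: str, cpg_positions: list[int] | None = None
) -> tuple[str, str]:
    """Converted reference forms of a plus-strand amplicon sequence.

    Forward form: C → T except CpG C → Y.  Reverse form (still written in plus
    orientation, describing the converted complementary strand): G → A except
    the G of each CpG → R.
    """
    seq = seq.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError(f"invalid DNA characters: {sorted(set(seq) - set('ACGTN'))}")
    if cpg_positions is None:
        cpg_positions = list_cpg_sites(seq)
    for p in cpg_positions:
        if not (0 <= p < len(seq) - 1 and seq[p] == "C" and seq[p + 1] == "G"):
            raise ValueError(f"position {p} is not the C of a CG dinucleotide")
    cpg = set(cpg_positions)
    fwd = [
        "Y" if (b == "C" and i in cpg) else ("T" if b == "C" else b)
        for i, b in enumerate(seq)
    ]
    rev = [
        "R" if (b == "G" and i - 1 in cpg) else ("A" if b == "G" else b)
        for i, b in enumerate(seq)
    ]
    return "".join(fwd), "".join(rev)


@dataclass
class AmpliconTemplate:
    """Amplicon sequence with its CpG sites and converted reference forms.

    ``primer_masks`` are 0-based half-open intervals excluded from methylation
    calling (primer-derived bases carry no biological methylation signal).
    """

    name: str
    seq: str
    cpg_positions: list[int] = field(default=None)  # type: ignore[assignment]
    primer_masks: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if self.cpg_positions is None:
            self.cpg_positions = list_cpg_sites(self.seq)
        self.forward_ref, self.reverse_ref = bisulfite_convert_template(
            self.seq, self.cpg_positions
        )

    def unmasked_sites(self) -> list[int]:
        return [
            p for p in self.cpg_positions
            if not any(s <= p < e for s, e in self.primer_masks)
        ]


@dataclass
class AlignmentResult:
    read_id: str
    template: str
    orientation: str  # "forward" | "reverse"
    start: int  # template interval, 0-based half-open
    end: int
    pairs: list[tuple[int | None, int | None]]  # (oriented-read idx, template idx)
    oriented_read: str  # the read as aligned (reverse-complemented if reverse)
    score: float
    max_attainable: float
    passed: bool | None = None
    unalignable: bool = False

    @property
    def score_fraction(self) -> float:
        return self.score / self.max_attainable


@njit(cache=False)
def _gotoh_fill(read, ref, smat, gap_open, gap_extend):  # pragma: no cover
    m, n = read.shape[0], ref.shape[0]
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), -1e18)  # gap in read (consumes template)
    F = np.full((m + 1, n + 1), -1e18)  # gap in template (consumes read)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = H[i, j - 1] + gap_open
            if E[i, j - 1] + gap_extend > e:
                e = E[i, j - 1] + gap_extend
            E[i, j] = e
            f = H[i - 1, j] + gap_open
            if F[i - 1, j] + gap_extend > f:
                f = F[i - 1, j] + gap_extend
            F[i, j] = f
            h = H[i - 1, j - 1] + smat[read[i - 1], ref[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            if h > best:  # strictly greater: first maximal cell wins
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


def _traceback(H, E, F, smat, gap_open, gap_extend, read_codes, ref_codes, bi, bj):
    """State-tracked traceback from the maximal cell.

    Tie-break order: diagonal, then gap in template (consume read), then gap
    in read (consume template).
    """
    pairs: list[tuple[int | None, int | None]] = []
    i, j = bi, bj
    state = "H"
    eps = 1e-9
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] <= eps:
                break
            diag = H[i - 1, j - 1] + smat[read_codes[i - 1], ref_codes[j - 1]]
            if abs(H[i, j] - diag) <= eps:
                pairs.append((i - 1, j - 1))
                i -= 1
                j -= 1
            elif abs(H[i, j] - F[i, j]) <= eps:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # read base vs gap in template
            pairs.append((i - 1, None))
            if abs(F[i, j] - (H[i - 1, j] + gap_open)) <= eps:
                state = "H"
            i -= 1
        else:  # state E: template base vs gap in read
            pairs.append((None, j - 1))
            if abs(E[i, j] - (H[i, j - 1] + gap_open)) <= eps:
                state = "H"
            j -= 1
    pairs.reverse()
    return pairs


def max_attainable_score(read_length: int, scoring: ScoringScheme) -> float:
    """Score of a gapless full-length perfect match: match × read length."""
    if read_length < 1:
        raise ValueError("read length must be ≥ 1")
    return scoring.match * read_length


def _align_one(read_codes, ref_codes, smat, scoring):
    H, E, F, best, bi, bj = _gotoh_fill(
        read_codes, ref_codes, smat, scoring.gap_open, scoring.gap_extend
    )
    return H, E, F, best, bi, bj


def local_alignment_score(
    query: str, reference: str, scoring: ScoringScheme | None = None
) -> float:
    """Affine-gap local alignment score of two raw sequences (one strand)."""
    if not query or not reference:
        raise ValueError("sequences must be non-empty")
    scoring = scoring or ScoringScheme()
    _, _, _, best, _, _ = _align_one(
        _encode(query), _encode(reference), scoring.matrix(), scoring
    )
    return float(best)


def align_read(
    read: str,
    template: AmpliconTemplate,
    scoring: ScoringScheme | None = None,
    read_id: str = "read",
) -> AlignmentResult:
    """Best local alignment of one read against both converted references."""
    if len(read) == 0:
        raise ValueError("empty read")
    scoring = scoring or ScoringScheme()
    smat = scoring.matrix()
    max_score = max_attainable_score(len(read), scoring)

    if set(read.upper()) <= {"N"}:
        return AlignmentResult(
            read_id, template.name, "forward", 0, 0, [], read.upper(),
            0.0, max_score, unalignable=True,
        )

    candidates = []
    for orientation, oriented, ref in (
        ("forward", read.upper(), template.forward_ref),
        ("reverse", revcomp(read.upper()), template.reverse_ref),
    ):
        rc = _encode(oriented)
        tc = _encode(ref)
        H, E, F, best, bi, bj = _align_one(rc, tc, smat, scoring)
        candidates.append((best, orientation, oriented, rc, tc, H, E, F, bi, bj))

    # ties break toward forward (its tuple comes first and > is strict)
    best = candidates[0]
    if candidates[1][0] > candidates[0][0]:
        best = candidates[1]
    score, orientation, oriented, rc, tc, H, E, F, bi, bj = best

    if score <= 0:
        return AlignmentResult(
            read_id, template.name, "forward", 0, 0, [], read.upper(),
            0.0, max_score, unalignable=True,
        )
    pairs = _traceback(
        H, E, F, smat, scoring.gap_open, scoring.gap_extend, rc, tc, bi, bj
    )
    tmpl_idx = [j for _, j in pairs if j is not None]
    return AlignmentResult(
        read_id, template.name, orientation,
        min(tmpl_idx), max(tmpl_idx) + 1, pairs, oriented,
        float(score), max_score,
    )


def filter_reads(
    alignments: list[AlignmentResult], min_fraction: float = 0.80
) -> list[AlignmentResult]:
    """Retain reads scoring at least ``min_fraction`` of their maximum.

    The threshold is inclusive ("a minimum of" the fraction); every input
    result's ``passed`` flag is set in place and the passing subset returned.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must lie in (0, 1]")
    passing = []
    for aln in alignments:
        aln.passed = (not aln.unalignable) and aln.score_fraction >= min_fraction
        if aln.passed:
            passing.append(aln)
    return passing
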