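"""Pairwise protein alignment and the randomized-alignment significance test.

Global (Needleman–Wunsch) and local (Smith–Waterman) affine-gap alignment run
on Biopython's C aligner behind a small, explicit scoring surface.  The
statistical machinery — composition-preserved shuffling and the Z-score /
confidence read-out against a shuffle null — is the part that decides cluster
membership downstream and is implemented here.

A gap of length k costs ``gap_open + k * gap_extend`` (BLAST convention), so
the first gapped residue costs ``gap_open + gap_extend``.  The default scheme
is BLOSUM62 with open 11 / extend 1; the ambiguity residue X scores 0 against
everything.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.stats import norm
from Bio import Align
from Bio.Align import substitution_matrices

ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"

#: one-sided normal confidence for grouping proteins into orthologous
#: clusters (z >= 4.7534)
CLUSTER_CONFIDENCE = 0.999999
#: one-sided normal confidence for calling an outgroup sequence a homolog
#: (z >= 2.3263)
HOMOLOG_CONFIDENCE = 0.99
#: number of composition-preserved shuffles in the null distribution
DEFAULT_N_SHUFFLES = 50


def default_matrix() -> substitution_matrices.Array:
    """BLOSUM62 restricted to the 20 standard residues + X, with X scored 0."""
    blosum = substitution_matrices.load("BLOSUM62")
    mat = substitution_matrices.Array(alphabet=ALPHABET, dims=2)
    for a in ALPHABET:
        for b in ALPHABET:
            if a == "X" or b == "X":
                mat[a, b] = 0.0
            else:
                mat[a, b] = blosum[a, b]
    return mat


def matrix_from_dict(scores: dict, alphabet: str) -> substitution_matrices.Array:
    """Build a substitution matrix from ``{(a, b): score}`` (symmetrized)."""
    mat = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for (a, b), s in scores.items():
        mat[a, b] = s
        mat[b, a] = s
    return mat


def read_matrix(path: str | Path) -> substitution_matrices.Array:
    """Read a substitution matrix in NCBI text format."""
    return substitution_matrices.read(str(path))


@dataclass
class ScoringScheme:
    """Substitution matrix plus affine gap penalties.

    ``gap_open`` and ``gap_extend`` are non-negative costs; a gap of length k
    costs ``gap_open + k * gap_extend``.
    """

    matrix: substitution_matrices.Array = field(default_factory=default_matrix)
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        arr = np.asarray(self.matrix)
        if not np.allclose(arr, arr.T):
            raise ValueError("substitution matrix must be symmetric")
        self._aligners: dict[str, Align.PairwiseAligner] = {}

    def aligner(self, mode: str) -> Align.PairwiseAligner:
        """A cached Biopython aligner in 'global' or 'local' mode."""
        if mode not in ("global", "local"):
            raise ValueError(f"unknown mode {mode!r}")
        if mode not in self._aligners:
            a = Align.PairwiseAligner()
            a.substitution_matrix = self.matrix
            a.open_gap_score = -(self.gap_open + self.gap_extend)
            a.extend_gap_score = -self.gap_extend
            a.mode = mode
            self._aligners[mode] = a
        return self._aligners[mode]

    def key(self) -> tuple:
        """Hashable identity used to check that two tables share a scheme."""
        return (self.matrix.alphabet, float(self.gap_open),
                float(self.gap_extend), np.asarray(self.matrix).tobytes())


@dataclass
class AlignmentResult:
    """Score and identity summary of one pairwise alignment."""

    score: float
    aligned_a: str
    aligned_b: str
    mode: str

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    @property
    def n_identities(self) -> int:
        return sum(x == y and x != "-"
                   for x, y in zip(self.aligned_a, self.aligned_b))

    @property
    def percent_identity(self) -> float:
        if self.n_columns == 0:
            return 0.0
        return 100.0 * self.n_identities / self.n_columns


def _first_alignment(aligner: Align.PairwiseAligner, a: str, b: str):
    alignments = aligner.align(a, b)
    return alignments[0]


def _result(aligner, a: str, b: str, mode: str) -> AlignmentResult:
    score = aligner.score(a, b)
    if mode == "local" and score <= 0:
        return AlignmentResult(score=max(score, 0.0), aligned_a="",
                               aligned_b="", mode=mode)
    alignment = _first_alignment(aligner, a, b)
    seq_a = "".join(alignment[0])
    seq_b = "".join(alignment[1])
    return AlignmentResult(score=score, aligned_a=seq_a, aligned_b=seq_b,
                           mode=mode)


def global_align(seq_a: str, seq_b: str,
                 scheme: Optional[ScoringScheme] = None) -> AlignmentResult:
    """Optimal affine-gap global alignment (terminal gaps penalized)."""
    if not seq_a or not seq_b:
        raise ValueError("global_align requires non-empty sequences")
    scheme = scheme or ScoringScheme()
    return _result(scheme.aligner("global"), seq_a, seq_b, "global")


def global_score(seq_a: str, seq_b: str, scheme: ScoringScheme) -> float:
    """Score-only global alignment (no traceback; fast path)."""
    if not seq_a or not seq_b:
        raise ValueError("global_score requires non-empty sequences")
    return scheme.aligner("global").score(seq_a, seq_b)


def local_align(seq_a: str, seq_b: str,
                scheme: Optional[ScoringScheme] = None) -> AlignmentResult:
    """Optimal affine-gap local alignment; the empty alignment (score 0)
    is returned when no positive-scoring segment pair exists."""
    if not seq_a or not seq_b:
        raise ValueError("local_align requires non-empty sequences")
    scheme = scheme or ScoringScheme()
    return _result(scheme.aligner("local"), seq_a, seq_b, "local")


def local_score(seq_a: str, seq_b: str, scheme: ScoringScheme) -> float:
    """Score-only local alignment (no traceback; fast path)."""
    if not seq_a or not seq_b:
        raise ValueError("local_score requires non-empty sequences")
    return max(0.0, scheme.aligner("local").score(seq_a, seq_b))


def shuffle_preserving_composition(seq: str, rng: np.random.Generator) -> str:
    """Uniform random permutation of the residues of ``seq``.

    Preserves the residue multiset exactly, destroying all positional signal;
    repeated draws build the null score distribution for the significance
    test.
    """
    if not seq:
        raise ValueError("cannot shuffle an empty sequence")
    chars = np.frombuffer(seq.encode("ascii"), dtype="S1")
    return rng.permutation(chars).tobytes().decode("ascii")


@dataclass
class SignificanceResult:
    """Observed score versus a composition-preserved shuffle null.

    ``z`` is (observed − null mean) / null SD with the sample (n−1) SD;
    ``confidence`` is the one-sided standard-normal probability Φ(z).  A
    degenerate null (SD = 0) yields confidence 1.0 when the observed score
    beats the null mean and 0.0 otherwise.
    """

    observed_score: float
    n_shuffles: int
    null_mean: float
    null_sd: float
    z: float
    confidence: float

    def significant(self, confidence_level: float) -> bool:
        return self.confidence > confidence_level


def randomized_significance(
    seq_a: str,
    seq_b: str,
    scheme: Optional[ScoringScheme] = None,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    rng: Optional[np.random.Generator] = None,
) -> SignificanceResult:
    """Composition-preserved randomization test for one sequence pair.

    Globally aligns ``seq_a`` against ``seq_b`` and against ``n_shuffles``
    residue permutations of ``seq_b``; the observed score is read against the
    null mean/SD as a one-sided Z-test.
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    scheme = scheme or ScoringScheme()
    rng = rng if rng is not None else np.random.default_rng()
    observed = global_score(seq_a, seq_b, scheme)
    null_scores = np.empty(n_shuffles)
    for i in range(n_shuffles):
        null_scores[i] = global_score(
            seq_a, shuffle_preserving_composition(seq_b, rng), scheme)
    null_mean = float(null_scores.mean())
    null_sd = float(null_scores.std(ddof=1))
    if null_sd > 0:
        z = (observed - null_mean) / null_sd
        confidence = float(norm.cdf(z))
    elif observed > null_mean:
        z, confidence = math.inf, 1.0
    elif observed < null_mean:
        z, confidence = -math.inf, 0.0
    else:
        z, confidence = 0.0, 0.0
    return SignificanceResult(observed_score=observed, n_shuffles=n_shuffles,
                              null_mean=null_mean, null_sd=null_sd,
                              z=z, confidence=confidence)


def confidence_to_z(confidence: float) -> float:
    """One-sided normal quantile for a confidence level (0.99 -> 2.3263)."""
    return float(norm.ppf(confidence))
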