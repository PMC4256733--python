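"""Local alignment primitives.

Sequence-vs-sequence Smith-Waterman goes through Biopython's
PairwiseAligner (C implementation).  Profile-vs-sequence alignment —
needed for PSSM searches, which no installed library provides — is a
small affine-gap DP compiled with numba.  E-values for profile hits are
empirical: scores of residue-shuffled sequences pooled over the
database are fitted with a Gumbel distribution by method of moments.
"""

from __future__ import annotations

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from numba import njit

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
X_CODE = 20  # unknown residue: scored 0 against every profile column

_EULER_GAMMA = 0.5772156649015329


def encode(seq: str) -> np.ndarray:
    """Map residues to integer codes 0..19; anything else becomes X (20)."""
    return np.fromiter((AA_INDEX.get(c, X_CODE) for c in seq.upper()),
                       dtype=np.int8, count=len(seq))


def load_substitution_matrix(name: str = "BLOSUM62"):
    return substitution_matrices.load(name)


def make_aligner(substitution_matrix="BLOSUM62", gap_open: float = 11,
                 gap_extend: float = 1, mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    if isinstance(substitution_matrix, str):
        substitution_matrix = load_substitution_matrix(substitution_matrix)
    aligner.substitution_matrix = substitution_matrix
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def sanitize(seq: str, alphabet) -> str:
    """Replace residues outside the substitution matrix alphabet with X."""
    allowed = set(alphabet)
    return "".join(c if c in allowed else "X" for c in seq.upper())


def local_align(aligner: Align.PairwiseAligner, a: str, b: str):
    """Best local alignment of two sequences.

    Returns ``(score, q_cov, s_cov)``; ``(0.0, 0.0, 0.0)`` when no
    positive-scoring local alignment exists.
    """
    alphabet = aligner.substitution_matrix.alphabet
    a2, b2 = sanitize(a, alphabet), sanitize(b, alphabet)
    score = aligner.score(a2, b2)
    if score <= 0:
        return 0.0, 0.0, 0.0
    aln = aligner.align(a2, b2)[0]
    spans = aln.aligned
    if len(spans[0]) == 0:
        return 0.0, 0.0, 0.0
    q_span = spans[0][-1][1] - spans[0][0][0]
    s_span = spans[1][-1][1] - spans[1][0][0]
    return float(score), q_span / len(a), s_span / len(b)


@njit(cache=True)
def _sw_profile_kernel(columns, seq, gap_open, gap_extend):
    """Affine-gap local DP of a profile (rows) against a coded sequence.

    Returns (score, profile_start, profile_end, seq_start, seq_end) with
    half-open [start, end) coordinates.  Cell starts are propagated so
    no traceback matrix is needed.
    """
    L = columns.shape[0]
    M = seq.shape[0]
    NEG = -1e30
    H = np.zeros((L + 1, M + 1))
    E = np.full((L + 1, M + 1), NEG)
    F = np.full((L + 1, M + 1), NEG)
    # start coordinates of the local path ending in each cell
    Hsi = np.zeros((L + 1, M + 1), dtype=np.int32)
    Hsj = np.zeros((L + 1, M + 1), dtype=np.int32)
    Esi = np.zeros((L + 1, M + 1), dtype=np.int32)
    Esj = np.zeros((L + 1, M + 1), dtype=np.int32)
    Fsi = np.zeros((L + 1, M + 1), dtype=np.int32)
    Fsj = np.zeros((L + 1, M + 1), dtype=np.int32)
    best = 0.0
    bi = 0
    bj = 0
    bsi = 0
    bsj = 0
    for i in range(1, L + 1):
        for j in range(1, M + 1):
            # E: gap in profile (consume sequence)
            open_e = H[i, j - 1] - gap_open
            ext_e = E[i, j - 1] - gap_extend
            if open_e >= ext_e:
                E[i, j] = open_e
                Esi[i, j] = Hsi[i, j - 1]
                Esj[i, j] = Hsj[i, j - 1]
            else:
                E[i, j] = ext_e
                Esi[i, j] = Esi[i, j - 1]
                Esj[i, j] = Esj[i, j - 1]
            # F: gap in sequence (consume profile)
            open_f = H[i - 1, j] - gap_open
            ext_f = F[i - 1, j] - gap_extend
            if open_f >= ext_f:
                F[i, j] = open_f
                Fsi[i, j] = Hsi[i - 1, j]
                Fsj[i, j] = Hsj[i - 1, j]
            else:
                F[i, j] = ext_f
                Fsi[i, j] = Fsi[i - 1, j]
                Fsj[i, j] = Fsj[i - 1, j]
            code = seq[j - 1]
            if code >= 20:
                sub = 0.0
            else:
                sub = columns[i - 1, code]
            diag = H[i - 1, j - 1] + sub
            si = Hsi[i - 1, j - 1]
            sj = Hsj[i - 1, j - 1]
            if H[i - 1, j - 1] == 0.0:
                si = i - 1
                sj = j - 1
            h = diag
            hsi = si
            hsj = sj
            if E[i, j] > h:
                h = E[i, j]
                hsi = Esi[i, j]
                hsj = Esj[i, j]
            if F[i, j] > h:
                h = F[i, j]
                hsi = Fsi[i, j]
                hsj = Fsj[i, j]
            if h < 0.0:
                h = 0.0
                hsi = i
                hsj = j
            H[i, j] = h
            Hsi[i, j] = hsi
            Hsj[i, j] = hsj
            if h > best:
                best = h
                bi = i
                bj = j
                bsi = hsi
                bsj = hsj
    return best, bsi, bi, bsj, bj


def sw_profile(columns: np.ndarray, coded_seq: np.ndarray,
               gap_open: float = 11.0, gap_extend: float = 1.0):
    """Profile-vs-sequence local alignment.

    Parameters
    ----------
    columns : (L, 20) float array of per-column residue scores.
    coded_seq : int8 array of residue codes (20 = unknown, scored 0).

    Returns (score, (p_start, p_end), (s_start, s_end)).
    """
    columns = np.ascontiguousarray(columns, dtype=np.float64)
    score, psi, pei, ssi, sei = _sw_profile_kernel(
        columns, coded_seq.astype(np.int8), float(gap_open), float(gap_extend))
    return float(score), (int(psi), int(pei)), (int(ssi), int(sei))


def fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """Method-of-moments Gumbel (location mu, scale beta) fit."""
    scores = np.asarray(scores, dtype=float)
    mean = scores.mean()
    sd = scores.std(ddof=1) if scores.size > 1 else 0.0
    beta = max(sd * np.sqrt(6.0) / np.pi, 1e-9)
    mu = mean - _EULER_GAMMA * beta
    return mu, beta


def gumbel_sf(x, mu: float, beta: float):
    """P(S >= x) for a Gumbel(mu, beta) right tail."""
    z = (np.asarray(x, dtype=float) - mu) / beta
    # stable 1 - exp(-exp(-z))
    return -np.expm1(-np.exp(-z))
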