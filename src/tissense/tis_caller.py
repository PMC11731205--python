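"""Statistical calling of translation-initiation sites from P-site tracks.

Harringtonine arrests initiating ribosomes on start codons, so an active
TIS shows up as a P-site pileup on its codon.  Each candidate codon's 3-nt
P-site sum is tested against a per-transcript negative-binomial background
(upper tail), and discoveries are controlled transcriptome-wide with
Benjamini-Hochberg.

The background is fitted on codon-binned counts after masking start-codon
positions (the positions that could carry initiation signal); masking is
defined by sequence alone, so under the null the retained bins are an
unbiased sample of the elongation background.  Dispersion is estimated by
the method of moments and the model degenerates to Poisson when the data
are underdispersed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import TranscriptRecord
from .psite import PSiteTrack

_BASES = "ACGT"
#: ATG plus every single-substitution neighbour (the near-cognate starts).
NEAR_COGNATE_START_CODONS = frozenset(
    {"ATG"}
    | {
        "ATG"[:i] + b + "ATG"[i + 1 :]
        for i in range(3)
        for b in _BASES
        if b != "ATG"[i]
    }
)
ATG_ONLY = frozenset({"ATG"})


class BackgroundError(ValueError):
    """Too little signal-free sequence to fit a background model."""


@dataclass
class TISCandidate:
    """A start-codon position with its P-site signal and test results."""

    transcript_id: str
    position: int
    codon: str
    psite_count: int
    background_mu: float | None = None
    dispersion: float | None = None
    p_value: float | None = None
    q_value: float | None = None
    significant: bool = False


@dataclass(frozen=True)
class NBBackground:
    """Per-transcript background: mean per codon and NB size parameter.

    ``size`` is the NB dispersion parameter k with variance mu + mu**2/k;
    ``size is None`` marks the Poisson limit (variance <= mean).
    """

    mu: float
    size: float | None
    n_codons: int

    def sf(self, counts) -> np.ndarray:
        """Upper-tail P(X >= count) for each count."""
        x = np.asarray(counts, dtype=float)
        if self.mu == 0:
            return np.where(x <= 0, 1.0, 0.0)
        if self.size is None:
            return stats.poisson.sf(x - 1, self.mu)
        p = self.size / (self.size + self.mu)
        return stats.nbinom.sf(x - 1, self.size, p)


def scan_start_codons(
    transcript: TranscriptRecord, codon_set: frozenset[str] = NEAR_COGNATE_START_CODONS
) -> np.ndarray:
    """All positions (any frame) whose 3-mer is in ``codon_set``."""
    seq = transcript.sequence
    return np.array(
        [i for i in range(len(seq) - 2) if seq[i : i + 3] in codon_set], dtype=np.int64
    )


def find_candidates(
    track: PSiteTrack,
    transcript: TranscriptRecord,
    codon_set: frozenset[str] = NEAR_COGNATE_START_CODONS,
    min_count: int = 5,
) -> list[TISCandidate]:
    """Candidate TISs: start-codon positions whose 3-nt P-site sum >= min_count."""
    if len(track.counts) != transcript.length:
        raise ValueError(
            f"{transcript.transcript_id}: track length {len(track.counts)} != "
            f"transcript length {transcript.length}"
        )
    positions = scan_start_codons(transcript, codon_set)
    if positions.size == 0:
        return []
    c = track.counts
    sums = c[positions] + c[positions + 1] + c[positions + 2]
    keep = sums >= min_count
    seq = transcript.sequence
    return [
        TISCandidate(
            transcript_id=transcript.transcript_id,
            position=int(p),
            codon=seq[p : p + 3],
            psite_count=int(s),
        )
        for p, s in zip(positions[keep], sums[keep])
    ]


def fit_background(
    track: PSiteTrack,
    candidates: list[TISCandidate] | np.ndarray,
    exclusion_radius: int = 1,
    min_codons: int = 20,
    min_dispersion: float = 0.1,
) -> NBBackground:
    """Fit the per-transcript NB background on codon-binned counts.

    ``candidates`` — TISCandidate objects or raw positions — are masked out
    together with ``exclusion_radius`` codons on each side.  The moment
    estimator gives size = mu^2/(var - mu), floored at ``min_dispersion``;
    underdispersed data fall back to Poisson (size None).
    """
    counts = track.counts
    n_bins = len(counts) // 3
    if n_bins == 0:
        raise BackgroundError(f"{track.transcript_id}: transcript shorter than one codon")
    bins = counts[: 3 * n_bins].reshape(n_bins, 3).sum(axis=1)
    keep = np.ones(n_bins, dtype=bool)
    positions = [
        c.position if isinstance(c, TISCandidate) else int(c) for c in candidates
    ]
    for pos in positions:
        lo = max(0, pos // 3 - exclusion_radius)
        hi = min(n_bins, (pos + 2) // 3 + exclusion_radius + 1)
        keep[lo:hi] = False
    bg = bins[keep]
    if bg.size < min_codons:
        raise BackgroundError(
            f"{track.transcript_id}: only {bg.size} background codons "
            f"(< {min_codons}) after masking {len(positions)} candidate positions"
        )
    mu = float(bg.mean())
    var = float(bg.var(ddof=1))
    if var <= mu or mu == 0.0:
        return NBBackground(mu=mu, size=None, n_codons=int(bg.size))
    size = max(mu * mu / (var - mu), min_dispersion)
    return NBBackground(mu=mu, size=size, n_codons=int(bg.size))


def pool_dispersion(backgrounds: list[NBBackground]) -> float | None:
    """Robust transcriptome-wide NB size: the median of per-transcript
    moment estimates.

    Per-transcript dispersion estimated from a few dozen codon bins is far
    too noisy to set far-tail probabilities — occasional large size
    estimates (or Poisson fallbacks) make tails too light and inflate the
    false-discovery rate.  Counts share one sampling process across
    transcripts, so sharing a single robust size (while keeping the mean
    per transcript) is the standard stabilization.  Returns ``None`` when
    every transcript is in the Poisson limit.
    """
    sizes = [bg.size for bg in backgrounds if bg.size is not None]
    return float(np.median(sizes)) if sizes else None


def test_candidates(
    candidates: list[TISCandidate], background: NBBackground
) -> list[TISCandidate]:
    """Attach upper-tail NB p-values: p = P(X >= observed count)."""
    if not candidates:
        return candidates
    pvals = background.sf([c.psite_count for c in candidates])
    for cand, p in zip(candidates, pvals):
        cand.background_mu = background.mu
        cand.dispersion = background.size
        cand.p_value = float(p)
    return candidates


def benjamini_hochberg(pvals, n_tests: int | None = None) -> np.ndarray:
    """BH q-values; ``n_tests`` may exceed len(pvals) when the supplied
    p-values are the smallest of a larger scanned family."""
    p = np.asarray(pvals, dtype=float)
    k = p.size
    m = k if n_tests is None else int(n_tests)
    if m < k:
        raise ValueError(f"n_tests {m} smaller than number of p-values {k}")
    if k == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, k + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(k)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def call_tis(
    candidates: list[TISCandidate],
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> list[TISCandidate]:
    """BH-correct pooled candidates and return the significant ones.

    ``n_tests`` should be the total number of scanned start-codon positions
    so that positions filtered out for low counts (whose p-values are
    necessarily large) still count toward the testing burden.
    """
    qvals = benjamini_hochberg([c.p_value for c in candidates], n_tests)
    significant = []
    for cand, q in zip(candidates, qvals):
        cand.q_value = float(q)
        cand.significant = bool(q < alpha)
        if cand.significant:
            significant.append(cand)
    return significant
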