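"""The 440-dimensional sequence feature vector extracted from a PSSM.

Seven feature families summarise a domain's PSI-BLAST log-odds profile
P (an L x 20 integer matrix, columns in PSSM order) and its sequence:

====== ===== ==========================================================
Group  Size  Description
====== ===== ==========================================================
G1       20  sqrt of the amino-acid composition, sqrt(N_j / L)
G2       40  per-column mean of the positive / negative PSSM scores
G3       20  autocorrelation of hydrophobicity-weighted profile scores,
             lags 1..10, positive and negative parts separately
G4       20  as G3 with side-chain mass in place of hydrophobicity
G5      140  per-column PSSM score autocorrelation, lags 1..7
G6      120  mean-square of sliding-segment average scores, segment
             lengths {4, 8, 16}, positive / negative parts
G7       80  per-column mutation position preference: weighted mean
             relative position, spread, terminal bias, edge preference
====== ===== ==========================================================

Throughout, P+ = max(P, 0) and P- = min(P, 0); lag and segment features
that a short domain cannot support are emitted as 0 (with a log warning)
so the vector length is always exactly 440.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .scales import KYTE_DOOLITTLE, PSSM_COLUMNS, SIDE_CHAIN_MASS, scale_vector

__all__ = [
    "FeatureParams",
    "N_FEATURES",
    "feature_labels",
    "g1_composition",
    "g2_mutation_means",
    "g3_hydrophobicity_autocorr",
    "g4_mass_autocorr",
    "g5_pssm_autocorr",
    "g6_segment_mean_square",
    "g7_position_preference",
    "extract_features",
]

logger = logging.getLogger(__name__)

#: Total feature-vector dimension (20+40+20+20+140+120+80).
N_FEATURES = 440

PROPERTY_LAGS = tuple(range(1, 11))  # G3/G4
PSSM_LAGS = tuple(range(1, 8))  # G5
SEGMENT_LENGTHS = (4, 8, 16)  # G6
G7_STATS = ("mean", "spread", "bias", "edge")


@dataclass(frozen=True)
class ResidueScales:
    """Residue property tables used by the autocorrelation families."""

    hydrophobicity: dict[str, float] = field(
        default_factory=lambda: dict(KYTE_DOOLITTLE)
    )
    side_chain_mass: dict[str, float] = field(
        default_factory=lambda: dict(SIDE_CHAIN_MASS)
    )


@dataclass(frozen=True)
class FeatureParams:
    """Tunables of the feature extractor (scales are config-replaceable)."""

    scales: ResidueScales = field(default_factory=ResidueScales)


def _scores(pssm) -> np.ndarray:
    """Accept a PSSM object (``.scores``) or a bare L x 20 array."""
    arr = np.asarray(getattr(pssm, "scores", pssm), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 20:
        raise ValueError(f"PSSM scores must be L x 20, got shape {arr.shape}")
    return arr


@lru_cache(maxsize=1)
def feature_labels() -> tuple[str, ...]:
    """Stable, unique, group-prefixed names for the 440 features."""
    labels: list[str] = []
    labels += [f"G1_comp_{a}" for a in PSSM_COLUMNS]
    labels += [f"G2_pos_{a}" for a in PSSM_COLUMNS]
    labels += [f"G2_neg_{a}" for a in PSSM_COLUMNS]
    labels += [f"G3_hydro_pos_k{k}" for k in PROPERTY_LAGS]
    labels += [f"G3_hydro_neg_k{k}" for k in PROPERTY_LAGS]
    labels += [f"G4_mass_pos_k{k}" for k in PROPERTY_LAGS]
    labels += [f"G4_mass_neg_k{k}" for k in PROPERTY_LAGS]
    labels += [f"G5_{a}_k{k}" for a in PSSM_COLUMNS for k in PSSM_LAGS]
    for sign in ("pos", "neg"):
        for k in SEGMENT_LENGTHS:
            labels += [f"G6_{sign}_k{k}_{a}" for a in PSSM_COLUMNS]
    labels += [f"G7_{a}_{s}" for a in PSSM_COLUMNS for s in G7_STATS]
    assert len(labels) == N_FEATURES and len(set(labels)) == N_FEATURES
    return tuple(labels)


def g1_composition(sequence: str) -> np.ndarray:
    """sqrt(N_j / L) for each of the 20 standard amino-acid types.

    Non-standard letters (e.g. X) count toward L but toward no N_j.
    """
    if not sequence:
        raise ValueError("empty sequence")
    L = len(sequence)
    seq = sequence.upper()
    return np.sqrt(np.array([seq.count(a) for a in PSSM_COLUMNS]) / L)


def g2_mutation_means(pssm) -> np.ndarray:
    """Per-column means of the positive and of the negative scores (40)."""
    P = _scores(pssm)
    return np.concatenate([P.clip(min=0).mean(axis=0), P.clip(max=0).mean(axis=0)])


def _lagged_products(signal: np.ndarray, lags, context: str) -> np.ndarray:
    L = signal.shape[0]
    out = np.zeros(len(lags))
    for i, k in enumerate(lags):
        if k >= L:
            logger.warning(
                "%s: lag %d undefined for length-%d domain; emitting 0", context, k, L
            )
            continue
        out[i] = float(signal[:-k] @ signal[k:]) / (L - k)
    return out


def _property_autocorr(pssm, prop: np.ndarray, context: str) -> np.ndarray:
    P = _scores(pssm)
    pos = P.clip(min=0) @ prop
    neg = P.clip(max=0) @ prop
    return np.concatenate(
        [
            _lagged_products(pos, PROPERTY_LAGS, context + "/pos"),
            _lagged_products(neg, PROPERTY_LAGS, context + "/neg"),
        ]
    )


def g3_hydrophobicity_autocorr(pssm, params: FeatureParams | None = None) -> np.ndarray:
    """Lag-1..10 autocorrelation of the hydrophobicity-weighted profile (20)."""
    params = params or FeatureParams()
    prop = scale_vector(params.scales.hydrophobicity)
    return _property_autocorr(pssm, prop, "G3")


def g4_mass_autocorr(pssm, params: FeatureParams | None = None) -> np.ndarray:
    """Lag-1..10 autocorrelation of the side-chain-mass-weighted profile (20)."""
    params = params or FeatureParams()
    prop = scale_vector(params.scales.side_chain_mass)
    return _property_autocorr(pssm, prop, "G4")


def g5_pssm_autocorr(pssm) -> np.ndarray:
    """Per-column raw-score autocorrelation at lags 1..7 (140).

    Order: column-major over amino acids, lag-minor
    (A:k1..k7, R:k1..k7, ...).
    """
    P = _scores(pssm)
    L = P.shape[0]
    out = np.zeros((20, len(PSSM_LAGS)))
    for i, k in enumerate(PSSM_LAGS):
        if k >= L:
            logger.warning("G5: lag %d undefined for length-%d domain", k, L)
            continue
        out[:, i] = (P[:-k] * P[k:]).sum(axis=0) / (L - k)
    return out.ravel()


def _segment_means(P: np.ndarray, k: int) -> np.ndarray:
    csum = np.vstack([np.zeros((1, P.shape[1])), np.cumsum(P, axis=0)])
    return (csum[k:] - csum[:-k]) / k


def g6_segment_mean_square(pssm) -> np.ndarray:
    """Mean-square of sliding-segment average scores (120).

    For each segment length k in {4, 8, 16} and each column j, the mean
    over all L-k+1 segments of the squared segment-average score, for
    the positive and negative score parts separately.  Order: all
    positive blocks (k=4, 8, 16), then all negative blocks.
    """
    P = _scores(pssm)
    L = P.shape[0]
    blocks = []
    for part in (P.clip(min=0), P.clip(max=0)):
        for k in SEGMENT_LENGTHS:
            if k > L:
                logger.warning(
                    "G6: segment length %d undefined for length-%d domain", k, L
                )
                blocks.append(np.zeros(20))
                continue
            blocks.append((_segment_means(part, k) ** 2).mean(axis=0))
    return np.concatenate(blocks)


def g7_position_preference(pssm) -> np.ndarray:
    """Positional statistics of each column's positive-score mass (80).

    With weights w_i = P+_{i,j} and relative positions r_i = i/L
    (1-based), per column: (a) weighted mean of r; (b) weighted standard
    deviation of r; (c) terminal bias, the N-half minus C-half weight
    fraction; (d) edge preference, the weighted mean of |r - 0.5|.
    A weightless column reports the neutral point (0.5, 0, 0, 0.25).
    """
    P = _scores(pssm)
    L = P.shape[0]
    r = np.arange(1, L + 1) / L
    half = int(np.ceil(L / 2))
    Wpos = P.clip(min=0)
    out = np.zeros((20, 4))
    for j in range(20):
        w = Wpos[:, j]
        W = w.sum()
        if W == 0:
            out[j] = (0.5, 0.0, 0.0, 0.25)
            continue
        mean = float(w @ r) / W
        spread = float(np.sqrt(w @ (r - mean) ** 2 / W))
        bias = float(w[:half].sum() - w[half:].sum()) / W
        edge = float(w @ np.abs(r - 0.5)) / W
        out[j] = (mean, spread, bias, edge)
    return out.ravel()


def extract_features(
    sequence: str, pssm, params: FeatureParams | None = None
) -> np.ndarray:
    """Concatenate G1..G7 into the 440D sequence feature vector."""
    params = params or FeatureParams()
    P = _scores(pssm)
    if len(sequence) != P.shape[0]:
        raise ValueError(
            f"sequence length {len(sequence)} != PSSM length {P.shape[0]}"
        )
    vec = np.concatenate(
        [
            g1_composition(sequence),
            g2_mutation_means(P),
            g3_hydrophobicity_autocorr(P, params),
            g4_mass_autocorr(P, params),
            g5_pssm_autocorr(P),
            g6_segment_mean_square(P),
            g7_position_preference(P),
        ]
    )
    assert vec.shape == (N_FEATURES,)
    return vec
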