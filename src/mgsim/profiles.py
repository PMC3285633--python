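"""Functional-category abundance profiles and their comparison.

A metagenome's functional content is summarized as a probability
distribution over functional categories (e.g. COGs): raw per-category
counts normalized to sum to one.  Profiles are compared by

* **Jensen-Shannon divergence** (log base 2, so JSD is bounded by 1 bit);
  the square root of the JSD is a proper metric and is the distance used
  for ordination;
* **PCoA** (classical multidimensional scaling) of a distance matrix;
* **PCA** of the sample x category probability matrix;
* **Pearson correlation** between an observed profile and the profile
  expected from the input genomes (each genome weighted by its share of
  community DNA, abundance x genome length, consistent with how reads are
  allocated).
"""
from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import rel_entr
from sklearn.decomposition import PCA

from . import io
from .community import CommunityProfile


@dataclass(frozen=True)
class AbundanceProfile:
    """A probability distribution over functional categories."""

    categories: tuple[str, ...]
    probabilities: np.ndarray

    def __post_init__(self):
        probs = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", probs)
        if len(self.categories) != probs.size:
            raise ValueError("categories and probabilities differ in length")
        if (probs < 0).any():
            raise ValueError("probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {probs.sum()}, not 1")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.categories, self.probabilities.tolist()))

    def to_tsv(self, path: str | os.PathLike) -> None:
        io.write_tsv(
            pd.DataFrame({"category": self.categories, "probability": self.probabilities}),
            path,
        )

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "AbundanceProfile":
        frame = pd.read_csv(path, sep="\t")
        col = "probability" if "probability" in frame.columns else "count"
        return normalize_abundance(
            dict(zip(frame.iloc[:, 0].astype(str), frame[col].astype(float)))
        )


def normalize_abundance(counts: dict[str, float]) -> AbundanceProfile:
    """Normalize raw category counts to a probability distribution."""
    cats = tuple(counts)
    values = np.array([counts[c] for c in cats], dtype=float)
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    total = values.sum()
    if total <= 0:
        raise ValueError("all counts are zero")
    return AbundanceProfile(cats, values / total)


def expected_profile(
    genome_counts: dict[str, dict[str, float]],
    profile: CommunityProfile,
    genome_lengths: dict[str, int],
) -> AbundanceProfile:
    """Category distribution expected from the input genomes.

    Each genome's category counts are weighted by its share of community
    DNA (abundance x genome length) and summed, then normalized — the same
    weighting that governs how many reads each genome receives.
    """
    totals: dict[str, float] = {}
    for genome_id in profile.genome_ids:
        if genome_id not in genome_counts:
            raise KeyError(f"no feature counts for genome {genome_id!r}")
        if genome_id not in genome_lengths:
            raise KeyError(f"no length for genome {genome_id!r}")
        w = profile.abundance_of(genome_id) * genome_lengths[genome_id]
        for cat, count in genome_counts[genome_id].items():
            totals[cat] = totals.get(cat, 0.0) + w * count
    return normalize_abundance(totals)


def align_profiles(p: AbundanceProfile, q: AbundanceProfile) -> tuple[np.ndarray, np.ndarray]:
    """Zero-fill both profiles onto the union of their category universes."""
    cats = sorted(set(p.categories) | set(q.categories))
    pd_, qd = p.as_dict(), q.as_dict()
    return (
        np.array([pd_.get(c, 0.0) for c in cats]),
        np.array([qd.get(c, 0.0) for c in cats]),
    )


def jensen_shannon_divergence(p: AbundanceProfile, q: AbundanceProfile) -> float:
    """JSD(P, Q) in bits: mean KL divergence of P and Q to their midpoint."""
    pv, qv = align_profiles(p, q)
    m = 0.5 * (pv + qv)
    jsd = 0.5 * rel_entr(pv, m).sum() + 0.5 * rel_entr(qv, m).sum()
    return float(jsd / np.log(2.0))


def jsd_distance(p: AbundanceProfile, q: AbundanceProfile) -> float:
    """The metric form: square root of the Jensen-Shannon divergence."""
    return float(np.sqrt(max(jensen_shannon_divergence(p, q), 0.0)))


def distance_matrix(profiles: list[AbundanceProfile]) -> np.ndarray:
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jsd_distance(profiles[i], profiles[j])
    return d


@dataclass
class OrdinationResult:
    """Sample coordinates on ordination axes, eigenvalue-ordered."""

    coordinates: np.ndarray  # samples x axes
    explained: np.ndarray  # fraction of (positive) variance per axis
    eigenvalues: np.ndarray
    negative_eigenvalues: np.ndarray = None  # PCoA diagnostics

    def to_frame(self, sample_ids: list[str] | None = None) -> pd.DataFrame:
        n, k = self.coordinates.shape
        frame = pd.DataFrame(
            self.coordinates, columns=[f"axis{i + 1}" for i in range(k)]
        )
        frame.insert(0, "sample", sample_ids if sample_ids is not None else range(n))
        return frame


def pcoa(distances: np.ndarray, tol: float = 1e-12) -> OrdinationResult:
    """Classical multidimensional scaling of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, and keeps the axes with
    positive eigenvalues; coordinates are eigenvectors scaled by the square
    roots of their eigenvalues.  Negative eigenvalues (from non-Euclidean
    distances) are dropped and reported in ``negative_eigenvalues``.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")

    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    cutoff = tol * max(abs(eigvals.max(initial=0.0)), 1.0)
    positive = eigvals > cutoff
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    pos_sum = eigvals[positive].sum()
    explained = eigvals[positive] / pos_sum if pos_sum > 0 else eigvals[positive]
    return OrdinationResult(
        coordinates=coords,
        explained=explained,
        eigenvalues=eigvals[positive],
        negative_eigenvalues=np.abs(eigvals[eigvals < -cutoff]),
    )


def pca(matrix: np.ndarray) -> OrdinationResult:
    """PCA of a samples x categories matrix (column mean-centering)."""
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    model = PCA()
    scores = model.fit_transform(x)
    return OrdinationResult(
        coordinates=scores,
        explained=model.explained_variance_ratio_,
        eigenvalues=model.explained_variance_,
    )


def pearson_correlation(expected: AbundanceProfile, observed: AbundanceProfile) -> float:
    """Pearson r between paired category probabilities (zero-filled union)."""
    ev, ov = align_profiles(expected, observed)
    if ev.size < 2:
        raise ValueError("need at least 2 categories")
    if np.allclose(ev, ev[0]) or np.allclose(ov, ov[0]):
        raise ValueError("zero variance in a profile")
    return float(stats.pearsonr(ev, ov).statistic)
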