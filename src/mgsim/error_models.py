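"""Quality-value models for the three sequencing platforms.

The central quantity is the per-base Phred quality Q and its error
probability P.  The default mapping is the odds form

    Q = -10 * log10(P / (1 - P))        (``convention="odds"``)

whose inverse is ``P = 1 / (1 + 10**(Q/10))``.  The conventional Phred
definition ``Q = -10 log10 P`` is available as ``convention="standard"``.

Quality models are per-cycle: an empirical model stores the observed
distribution of quality values at each cycle of a run (loaded from .qual
files); a parametric model stores a (mean, sd) pair per cycle.  Runs can be
clustered by the Euclidean distance between their per-cycle mean-quality
vectors to obtain a small set of representative machine/protocol models.

The built-in defaults are parametric stand-ins calibrated to typical
platform behaviour, used when no empirical .qual files are supplied:

* Illumina: fixed-length reads with linearly decaying quality (Q 35 -> 25
  over 75 cycles by default);
* Sanger: variable-length reads whose quality rises over the first ~100
  bases, plateaus, and falls towards the 3' end;
* pyrosequencing: near-constant quality (Q 28) with homopolymer-length
  errors handled downstream by the read simulator.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.cluster import KMeans

from . import io
from .io import MAX_QUAL

_CONVENTIONS = ("odds", "standard")


def _check_convention(convention: str) -> None:
    if convention not in _CONVENTIONS:
        raise ValueError(f"convention must be one of {_CONVENTIONS}")


def phred_to_error_prob(q, convention: str = "odds"):
    """Error probability for Phred quality ``q``.

    ``odds``: P = 1 / (1 + 10**(Q/10)); ``standard``: P = 10**(-Q/10).
    Strictly decreasing in Q under both conventions.
    """
    _check_convention(convention)
    q_arr = np.asarray(q, dtype=float)
    if (q_arr < 0).any():
        raise ValueError("quality scores must be non-negative")
    if convention == "odds":
        p = 1.0 / (1.0 + 10.0 ** (q_arr / 10.0))
    else:
        p = 10.0 ** (-q_arr / 10.0)
    return p.item() if np.isscalar(q) else p


def error_prob_to_phred(p, convention: str = "odds"):
    """Phred quality for error probability ``p`` in (0, 1)."""
    _check_convention(convention)
    p_arr = np.asarray(p, dtype=float)
    if ((p_arr <= 0) | (p_arr >= 1)).any():
        raise ValueError("error probability must be in the open interval (0, 1)")
    if convention == "odds":
        q = -10.0 * np.log10(p_arr / (1.0 - p_arr))
    else:
        q = -10.0 * np.log10(p_arr)
    return q.item() if np.isscalar(p) else q


@dataclass
class QualityProfile:
    """Per-cycle quality model for one platform.

    Exactly one of two shapes:

    * empirical — ``histograms[c, q]`` counts occurrences of quality ``q``
      at cycle ``c`` across the reads of a run (fixed read length);
    * parametric — per-cycle ``means``/``sds``; for variable-length
      platforms ``mean_fn(length)`` / ``sd_fn(length)`` produce the
      per-position curves for a read of a given length.
    """

    platform: str
    label: str = ""
    read_length: int | None = None  # None = variable-length platform
    means: np.ndarray | None = None
    sds: np.ndarray | None = None
    histograms: np.ndarray | None = None  # (read_length, MAX_QUAL + 1)
    mean_fn: Callable[[int], np.ndarray] | None = field(default=None, repr=False)
    sd_fn: Callable[[int], np.ndarray] | None = field(default=None, repr=False)
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.histograms is not None:
            self.histograms = np.asarray(self.histograms, dtype=float)
            if self.read_length is None:
                self.read_length = self.histograms.shape[0]
            if self.histograms.shape != (self.read_length, MAX_QUAL + 1):
                raise ValueError("histograms must be (read_length, 94)")
            totals = self.histograms.sum(axis=1)
            if (totals <= 0).any():
                raise ValueError("every cycle needs at least one observation")
            qvals = np.arange(MAX_QUAL + 1, dtype=float)
            probs = self.histograms / totals[:, None]
            self.means = probs @ qvals
            self.sds = np.sqrt(np.maximum(probs @ qvals**2 - self.means**2, 0.0))
        if self.means is not None:
            self.means = np.asarray(self.means, dtype=float)
            if (self.means < 0).any() or (self.means > MAX_QUAL).any():
                raise ValueError(f"mean qualities must lie in [0, {MAX_QUAL}]")
            if self.sds is None:
                self.sds = np.zeros_like(self.means)
            self.sds = np.asarray(self.sds, dtype=float)
            if self.read_length is not None and self.means.size != self.read_length:
                raise ValueError("per-cycle model length != read_length")

    @property
    def kind(self) -> str:
        return "empirical" if self.histograms is not None else "parametric"

    @property
    def n_cycles(self) -> int:
        if self.read_length is not None:
            return self.read_length
        raise ValueError("variable-length profile has no fixed cycle count")

    def per_cycle_means(self, length: int | None = None) -> np.ndarray:
        if self.means is not None:
            return self.means if length is None else self.means[:length]
        if self.mean_fn is not None:
            if length is None:
                raise ValueError("variable-length profile needs an explicit length")
            return np.asarray(self.mean_fn(length), dtype=float)
        raise ValueError("profile defines no quality curve")

    def per_cycle_sds(self, length: int | None = None) -> np.ndarray:
        if self.sds is not None and self.means is not None:
            return self.sds if length is None else self.sds[:length]
        if self.sd_fn is not None:
            return np.asarray(self.sd_fn(length), dtype=float)
        return np.zeros(length if length is not None else 0)

    def sample(self, length: int, rng: np.random.Generator) -> np.ndarray:
        """Draw one quality vector of ``length`` values in [0, MAX_QUAL]."""
        if length == 0:
            return np.zeros(0, dtype=int)
        if self.read_length is not None and length > self.read_length:
            raise ValueError(
                f"requested length {length} exceeds model support {self.read_length}"
            )
        if self.histograms is not None:
            u = rng.random(length)
            cdf = np.cumsum(self.histograms[:length], axis=1)
            cdf /= cdf[:, -1:]
            quals = np.array(
                [np.searchsorted(cdf[c], u[c], side="right") for c in range(length)]
            )
        else:
            means = self.per_cycle_means(length)
            sds = self.per_cycle_sds(length)
            quals = np.rint(rng.normal(means[:length], sds[:length]))
        return np.clip(quals, 0, MAX_QUAL).astype(int)


def sample_quality_string(model: QualityProfile, length: int, rng: np.random.Generator) -> np.ndarray:
    """Sample a per-base quality vector from ``model`` (see ``QualityProfile.sample``)."""
    return model.sample(length, rng)


def load_qual_profiles(
    paths: Sequence[str | os.PathLike],
    platform: str = "illumina",
    fixed_length: bool = True,
) -> list[QualityProfile]:
    """Load one empirical per-cycle profile per .qual file (= per run).

    The cycle-``c`` distribution pools the c-th quality value of every
    record in the file.  For a fixed-length platform all records in a run
    must share one read length.
    """
    profiles = []
    for path in paths:
        records = io.read_qual(path)
        if not records:
            raise ValueError(f"{path}: no quality records")
        lengths = {len(q) for _, q in records}
        if fixed_length and len(lengths) > 1:
            raise ValueError(
                f"{path}: mixed read lengths {sorted(lengths)} in a fixed-length run"
            )
        read_length = max(lengths)
        hist = np.zeros((read_length, MAX_QUAL + 1))
        for _, quals in records:
            hist[np.arange(quals.size), quals] += 1
        if not fixed_length:
            # drop tail cycles seen in no record (cannot happen: max length)
            pass
        label = os.path.splitext(os.path.basename(str(path)))[0]
        profiles.append(
            QualityProfile(platform=platform, label=label, read_length=read_length,
                           histograms=hist)
        )
    return profiles


def cluster_profiles(
    profiles: Sequence[QualityProfile],
    k: int,
    seed: int = 0,
) -> tuple[np.ndarray, list[QualityProfile]]:
    """Cluster runs by Euclidean distance between per-cycle mean qualities.

    K-means partitions the per-cycle mean-quality vectors into ``k`` groups;
    the returned centroids are consensus parametric profiles (centroid mean
    per cycle, pooled member sd per cycle).

    Returns ``(labels, centroid_profiles)``.
    """
    if not profiles:
        raise ValueError("no profiles to cluster")
    if not 1 <= k <= len(profiles):
        raise ValueError(f"k must be in [1, {len(profiles)}]")
    lengths = {p.n_cycles for p in profiles}
    if len(lengths) > 1:
        raise ValueError(f"profiles mix read lengths {sorted(lengths)}; cluster per length")
    matrix = np.vstack([p.per_cycle_means() for p in profiles])
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(matrix)
    centroids = []
    for c in range(k):
        members = [p for p, lab in zip(profiles, labels) if lab == c]
        sds = np.vstack([p.per_cycle_sds() for p in members]).mean(axis=0)
        centroids.append(
            QualityProfile(
                platform=profiles[0].platform,
                label=f"cluster{c}",
                read_length=int(next(iter(lengths))),
                means=km.cluster_centers_[c],
                sds=sds,
                params={"members": [p.label for p in members]},
            )
        )
    return labels, centroids


def fit_positional_quality_model(profile: QualityProfile, family: str = "linear_decay") -> QualityProfile:
    """Least-squares fit of mean quality against cycle index.

    Families: ``constant`` (flat), ``linear_decay`` (straight line in the
    0-based cycle index), ``piecewise`` (two joined lines, breakpoint chosen
    by exhaustive SSE search).  Per-cycle residual sds are retained so the
    fitted model can still be sampled from.
    """
    y = profile.per_cycle_means()
    n = y.size
    if n == 0:
        raise ValueError("empty profile")
    x = np.arange(n, dtype=float)

    if family == "constant":
        fitted = np.full(n, y.mean())
        params = {"q": float(y.mean())}
    elif family == "linear_decay":
        if n < 2:
            raise ValueError("linear_decay needs at least 2 cycles")
        slope, intercept = np.polyfit(x, y, 1)
        fitted = intercept + slope * x
        params = {"slope": float(slope), "intercept": float(intercept)}
    elif family == "piecewise":
        if n < 4:
            raise ValueError("piecewise needs at least 4 cycles")
        best = None
        for b in range(2, n - 1):
            s1, i1 = np.polyfit(x[:b], y[:b], 1)
            s2, i2 = np.polyfit(x[b:], y[b:], 1)
            f = np.concatenate([i1 + s1 * x[:b], i2 + s2 * x[b:]])
            sse = float(((y - f) ** 2).sum())
            if best is None or sse < best[0]:
                best = (sse, b, f, {"breakpoint": b, "slope1": float(s1),
                                    "intercept1": float(i1), "slope2": float(s2),
                                    "intercept2": float(i2)})
        _, _, fitted, params = best
    else:
        raise ValueError(f"unknown family {family!r}")

    residual_sd = np.abs(y - fitted)
    # keep the larger of fit residual and the run's own per-cycle sd
    sds = np.maximum(residual_sd, profile.per_cycle_sds())
    params["family"] = family
    params["residual_sse"] = float(((y - fitted) ** 2).sum())
    return QualityProfile(
        platform=profile.platform,
        label=f"{profile.label}:{family}",
        read_length=n,
        means=np.clip(fitted, 0, MAX_QUAL),
        sds=sds,
        params=params,
    )


# ---------------------------------------------------------------------------
# built-in default models


def default_illumina_profile(read_length: int = 75, q_start: float = 35.0,
                             q_end: float = 25.0, sd: float = 3.0,
                             label: str = "illumina-default") -> QualityProfile:
    """Linear-decay Illumina model: mean quality falls q_start -> q_end."""
    means = np.linspace(q_start, q_end, read_length)
    return QualityProfile(
        platform="illumina", label=label, read_length=read_length,
        means=means, sds=np.full(read_length, sd),
        params={"q_start": q_start, "q_end": q_end},
    )


def default_sanger_profile(sd: float = 5.0) -> QualityProfile:
    """Sanger rise-plateau-fall model.

    Quality climbs from ~Q15 to ~Q40 over the first 100 bases, stays on the
    plateau until 85% of the read, then falls back towards Q15 at the 3' end.
    """

    def mean_fn(length: int) -> np.ndarray:
        pos = np.arange(length, dtype=float)
        means = np.full(length, 40.0)
        rise = pos < 100
        means[rise] = 15.0 + 25.0 * pos[rise] / 100.0
        fall_start = max(int(0.85 * length), 100)
        fall = pos >= fall_start
        if fall.any() and length - fall_start > 0:
            frac = (pos[fall] - fall_start) / max(length - fall_start, 1)
            means[fall] = np.minimum(means[fall], 40.0 - 25.0 * frac)
        return means

    return QualityProfile(
        platform="sanger", label="sanger-default", read_length=None,
        mean_fn=mean_fn, sd_fn=lambda length: np.full(length, sd),
    )


def default_pyro_profile(q: float = 28.0, sd: float = 3.0) -> QualityProfile:
    """Pyrosequencing model: constant mean quality (homopolymer indels are
    injected separately by the read simulator)."""
    return QualityProfile(
        platform="pyro", label="pyro-default", read_length=None,
        mean_fn=lambda length: np.full(length, q),
        sd_fn=lambda length: np.full(length, sd),
        params={"q": q},
    )


def default_profile(platform: str, read_length: int = 75) -> QualityProfile:
    if platform == "illumina":
        return default_illumina_profile(read_length=read_length)
    if platform == "sanger":
        return default_sanger_profile()
    if platform == "pyro":
        return default_pyro_profile()
    raise ValueError(f"unknown platform {platform!r}")


def save_profile_tsv(profile: QualityProfile, path: str | os.PathLike) -> None:
    """Serialize a fixed-length model as cycle <tab> mean <tab> sd."""
    import pandas as pd

    frame = pd.DataFrame(
        {
            "cycle": np.arange(profile.n_cycles),
            "mean": profile.per_cycle_means(),
            "sd": profile.per_cycle_sds(),
        }
    )
    io.write_tsv(frame, path)


def load_profile_tsv(path: str | os.PathLike, platform: str = "illumina",
                     label: str = "") -> QualityProfile:
    import pandas as pd

    frame = pd.read_csv(path, sep="\t")
    return QualityProfile(
        platform=platform,
        label=label or os.path.splitext(os.path.basename(str(path)))[0],
        read_length=len(frame),
        means=frame["mean"].to_numpy(float),
        sds=frame["sd"].to_numpy(float),
    )
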