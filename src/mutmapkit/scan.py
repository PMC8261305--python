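"""Variant-index genome scan: index, smoothing, null threshold, regions.

The variant index at a marker is the alternate-allele read fraction in the
phenotype-selected pool; for a recessive trait it drifts from ~0.5 at
unlinked markers towards 1 at the causal locus. The scan smooths the index
per chromosome, derives a genome-wide significance threshold from a
simulated null, and reports contiguous above-threshold regions with their
summit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import POOL_SAMPLE
from .smooth import SmoothingParams, lowess_batch

__all__ = [
    "variant_index",
    "build_index_track",
    "CandidateRegion",
    "null_index_threshold",
    "detect_candidate_regions",
    "genome_scan",
    "ScanResult",
    "DEFAULT_MORGANS_PER_BP",
]

log = logging.getLogger(__name__)

# genome-average recombination rate used when no genetic map is supplied
# (0.7 cM/Mb, a typical maize-scale figure)
DEFAULT_MORGANS_PER_BP = 0.7e-8


def variant_index(ref_count: int, alt_count: int) -> float:
    """Alternate-allele read fraction alt/(ref+alt)."""
    total = ref_count + alt_count
    if total < 1:
        raise ValueError("variant index undefined at zero total depth")
    return alt_count / total


def build_index_track(markers, pool_sample: str = POOL_SAMPLE) -> pd.DataFrame:
    """Index track DataFrame (chrom, pos, ref_count, alt_count, variant_index)
    from a marker set.

    Markers with zero pool depth are excluded (logged); duplicate positions on
    one chromosome are merged by summing read counts (a depth-weighted average
    of their indices) so the abscissa is strictly increasing per chromosome.
    """
    rows = []
    n_zero = 0
    for m in markers:
        r, a = m.depth_of(pool_sample)
        if r + a == 0:
            n_zero += 1
            continue
        rows.append((m.chrom, m.pos, r, a))
    if n_zero:
        log.warning("excluded %d markers with zero pool depth", n_zero)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref_count", "alt_count"])
    if df.duplicated(["chrom", "pos"]).any():
        df = df.groupby(["chrom", "pos"], as_index=False, sort=False).sum()
    df = df.sort_values(["chrom", "pos"], kind="mergesort", ignore_index=True)
    df["variant_index"] = df["alt_count"] / (df["ref_count"] + df["alt_count"])
    df.attrs["n_zero_depth_excluded"] = n_zero
    return df


def _smooth_track(df: pd.DataFrame, params: SmoothingParams) -> pd.DataFrame:
    """Add a smoothed_index column, LOWESS per chromosome, clipped to [0, 1]."""
    out = df.copy()
    smoothed = np.empty(len(df))
    for chrom, sub in df.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        if len(sub) < 2:
            log.warning("chromosome %s has <2 markers; copying raw index", chrom)
            smoothed[idx] = sub["variant_index"].to_numpy()
            continue
        y = lowess_batch(
            sub["pos"].to_numpy(float), sub["variant_index"].to_numpy()[None, :], params
        )[0]
        if (y < 0).any() or (y > 1).any():
            log.warning("clipping smoothed index outside [0,1] on %s", chrom)
            y = np.clip(y, 0.0, 1.0)
        smoothed[idx] = y
    out["smoothed_index"] = smoothed
    return out


def _null_max_smoothed(
    pos: np.ndarray,
    depths: np.ndarray,
    n_sims: int,
    params: SmoothingParams,
    pool_size,
    morgans_per_bp: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-replicate maxima of the smoothed null index on one chromosome.

    Null model: pooled allele frequency 0.5 plus, when pool_size is given,
    the bulk-sampling drift of a finite pool — a Gaussian AR(1) along the
    chromosome with per-marker variance 1/(8*pool_size) and inter-marker
    correlation exp(-2d) (the first two moments of the two-state Markov
    gamete model) — then binomial read sampling at the observed depths.
    """
    n = pos.size
    if pool_size is not None and n > 0:
        g = np.empty((n_sims, n))
        g[:, 0] = rng.standard_normal(n_sims)
        d = np.diff(pos) * morgans_per_bp
        rho = np.exp(-2.0 * d)
        innov = rng.standard_normal((n_sims, n - 1))
        for j in range(1, n):
            g[:, j] = rho[j - 1] * g[:, j - 1] + np.sqrt(1 - rho[j - 1] ** 2) * innov[:, j - 1]
        f = np.clip(0.5 + g / np.sqrt(8.0 * pool_size), 0.0, 1.0)
    else:
        f = np.full((n_sims, n), 0.5)
    alt = rng.binomial(depths[None, :], f)
    y = alt / depths[None, :]
    if n < 2:
        sm = y
    else:
        sm = np.clip(lowess_batch(pos.astype(float), y, params), 0.0, 1.0)
    return sm.max(axis=1)


def null_index_threshold(
    track: pd.DataFrame,
    params: SmoothingParams | None = None,
    q: float = 0.95,
    n_sims: int = 100,
    pool_size: int | None = None,
    morgans_per_bp: float | dict = DEFAULT_MORGANS_PER_BP,
    rng: np.random.Generator | int = 0,
) -> float:
    """q-quantile of the genome-wide maximum smoothed index under the null.

    Replicate unlinked tracks are simulated at the observed marker positions
    and depths, smoothed with the same parameters as the data, and the
    q-quantile of their genome-wide maxima is returned. ``pool_size`` adds the
    finite-bulk drift component; ``None`` keeps the pure binomial null.
    """
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    params = params or SmoothingParams()
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    maxima = np.full(n_sims, -np.inf)
    for chrom, sub in track.groupby("chrom", sort=False):
        mpb = morgans_per_bp[chrom] if isinstance(morgans_per_bp, dict) else morgans_per_bp
        m = _null_max_smoothed(
            sub["pos"].to_numpy(),
            (sub["ref_count"] + sub["alt_count"]).to_numpy(),
            n_sims,
            params,
            pool_size,
            mpb,
            rng,
        )
        maxima = np.maximum(maxima, m)
    return float(np.quantile(maxima, q))


@dataclass(frozen=True)
class CandidateRegion:
    chrom: str
    start_bp: int
    end_bp: int
    summit_pos: int
    summit_value: float
    n_markers: int

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom,
            "start_bp": self.start_bp,
            "end_bp": self.end_bp,
            "summit_pos": self.summit_pos,
            "summit_value": self.summit_value,
            "n_markers": self.n_markers,
        }


def detect_candidate_regions(
    track: pd.DataFrame,
    threshold: float,
    merge_gap_bp: float | dict | None = None,
) -> list[CandidateRegion]:
    """Maximal runs of consecutive markers with smoothed index >= threshold.

    Region boundaries snap to marker positions. Runs on the same chromosome
    separated by less than ``merge_gap_bp`` are merged — threshold-crossing
    noise at the scale of the smoothing window should not fragment one peak.
    The summit is the leftmost position of the maximum smoothed value.
    """
    if "smoothed_index" not in track.columns:
        raise ValueError("track must be smoothed first")
    regions: list[CandidateRegion] = []
    for chrom, sub in track.groupby("chrom", sort=False):
        gap = merge_gap_bp.get(chrom, 0.0) if isinstance(merge_gap_bp, dict) else (merge_gap_bp or 0.0)
        pos = sub["pos"].to_numpy()
        val = sub["smoothed_index"].to_numpy()
        above = val >= threshold
        if not above.any():
            continue
        # run boundaries as index pairs [i, j] inclusive
        edges = np.flatnonzero(np.diff(above.astype(int)))
        starts = [0] if above[0] else []
        starts += [e + 1 for e in edges if above[e + 1]]
        ends = [e for e in edges if above[e]]
        if above[-1]:
            ends.append(len(above) - 1)
        runs = list(zip(starts, ends))
        merged = [runs[0]]
        for s, e in runs[1:]:
            ps, pe = merged[-1]
            if pos[s] - pos[pe] < gap:
                merged[-1] = (ps, e)
            else:
                merged.append((s, e))
        for s, e in merged:
            seg = val[s : e + 1]
            k = s + int(np.argmax(seg))  # argmax: leftmost tie
            regions.append(
                CandidateRegion(
                    chrom=str(chrom),
                    start_bp=int(pos[s]),
                    end_bp=int(pos[e]),
                    summit_pos=int(pos[k]),
                    summit_value=float(val[k]),
                    n_markers=int(e - s + 1),
                )
            )
    return regions


@dataclass
class ScanResult:
    track: pd.DataFrame
    threshold: float
    regions: list[CandidateRegion]
    summit: CandidateRegion | None
    report: dict = field(default_factory=dict)


def genome_scan(
    markers,
    pool_sample: str = POOL_SAMPLE,
    params: SmoothingParams | None = None,
    q: float = 0.95,
    n_sims: int = 100,
    pool_size: int | None = 200,
    morgans_per_bp: float | dict = DEFAULT_MORGANS_PER_BP,
    merge_gap_fraction: float = 1.0,
    seed: int = 0,
) -> ScanResult:
    """Full scan: index -> per-chromosome LOWESS -> null threshold -> regions.

    ``merge_gap_fraction`` sets the run-merging gap as a fraction of each
    chromosome's marker span. The default 1.0 merges all above-threshold runs
    on one chromosome into a single region: linkage elevates an entire
    chromosome's track, so its excursions above the threshold are one
    dependent signal, not separate candidates. The global summit is the
    highest region summit, ties broken by (chrom, pos) order.
    """
    params = params or SmoothingParams()
    track = build_index_track(markers, pool_sample)
    if track.empty:
        raise ValueError("no markers with nonzero pool depth")
    track = _smooth_track(track, params)
    threshold = null_index_threshold(
        track,
        params=params,
        q=q,
        n_sims=n_sims,
        pool_size=pool_size,
        morgans_per_bp=morgans_per_bp,
        rng=np.random.default_rng(seed),
    )
    gaps = {
        str(chrom): merge_gap_fraction * float(sub["pos"].max() - sub["pos"].min())
        for chrom, sub in track.groupby("chrom", sort=False)
    }
    regions = detect_candidate_regions(track, threshold, merge_gap_bp=gaps)
    summit = max(regions, key=lambda r: r.summit_value) if regions else None
    report = {
        "n_markers": int(len(track)),
        "n_zero_depth_excluded": int(track.attrs.get("n_zero_depth_excluded", 0)),
        "smoothing": {"span_fraction": params.span_fraction,
                      "robustness_iterations": params.robustness_iterations},
        "null": {"q": q, "n_sims": n_sims, "pool_size": pool_size, "seed": seed},
        "threshold": threshold,
        "regions": [r.to_dict() for r in regions],
        "summit": summit.to_dict() if summit else None,
    }
    return ScanResult(track=track, threshold=threshold, regions=regions, summit=summit, report=report)
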