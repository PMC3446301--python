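"""Replication profiles from S-phase and G2 read coverage.

The copy-number replication profile is built exactly as in HU-arrest
replication profiling: reads are extended 100 bp in the 3' direction (the
sequenced fragments average ~200 bp), coverage is counted in 200-bp windows
stepped every 20 bp, each dataset is normalized to genome mean 1, and the
two samples are combined with

    R = S * (1 + n) - G2 + 1

where ``n`` is the fraction of the genome replicated in the S sample
(measured by flow cytometry on real data; derived from the planted intensity
on synthetic data).  With mean-1 inputs this restores S to its true mean copy
number ``1 + n``, so R has baseline 1 and peak height equal to local copy
number.  Finally R is smoothed with LOESS (degree-1 locally weighted
regression, tricube weights).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .track import BinnedTrack

__all__ = [
    "ProfileParams",
    "ReplicationProfile",
    "bin_reads",
    "normalize_mean_one",
    "combine_replication",
    "loess_smooth",
    "build_profile",
]

log = logging.getLogger(__name__)


@dataclass
class ProfileParams:
    """Parameters of profile construction."""

    window: int = 200
    step: int = 20
    read_extension: int = 100     # bp added in the 3' direction
    replicated_fraction_n: float = 0.0
    loess_span: float = 0.001     # fraction of bins per local fit; dataset-specific
    loess_window_bp: int | None = 3000  # when set, overrides loess_span per chromosome
    exclusion_intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.replicated_fraction_n <= 1:
            raise ValueError("replicated_fraction_n must be in [0, 1]")
        if not 0 < self.loess_span <= 1:
            raise ValueError("loess_span must be in (0, 1]")


@dataclass
class ReplicationProfile:
    """A combined replication profile R with provenance."""

    R: BinnedTrack
    provenance: dict = field(default_factory=dict)


def bin_reads(
    reads: pd.DataFrame,
    chrom_lengths: dict[str, int],
    params: ProfileParams | None = None,
) -> BinnedTrack:
    """Bin stranded reads into a sliding-window coverage track.

    Each read is extended ``read_extension`` bp 3'-ward (rightward for '+'
    reads, leftward for '-'), and each bin counts the extended reads whose
    interval overlaps the bin's window.  Reads running past a chromosome end
    are clipped and counted in the log; an unknown chromosome raises.
    """
    params = params or ProfileParams()
    track = BinnedTrack(chrom_lengths=dict(chrom_lengths), window=params.window, step=params.step)
    if len(reads):
        strand = reads["strand"].to_numpy()
        start = reads["start"].to_numpy(dtype=np.int64)
        end = reads["end"].to_numpy(dtype=np.int64)
        ext_start = np.where(strand == "-", start - params.read_extension, start)
        ext_end = np.where(strand == "-", end, end + params.read_extension)
        clipped = track.add_intervals(zip(reads["chrom"], ext_start, ext_end))
        if clipped:
            log.info("bin_reads: clipped %d reads at chromosome boundaries", clipped)
    if params.exclusion_intervals:
        track.mask_intervals(params.exclusion_intervals)
    return track


def normalize_mean_one(track: BinnedTrack) -> BinnedTrack:
    """Scale unmasked bins so their genome-wide mean is exactly 1.

    Masked bins are left unchanged.  An all-zero track cannot be normalized.
    """
    mean = track.mean()
    if mean <= 0:
        raise ValueError("cannot normalize: unmasked mean is not positive")
    out = track.copy()
    for chrom in out.chroms:
        keep = ~out.mask[chrom]
        out.values[chrom][keep] = out.values[chrom][keep] / mean
    return out


def combine_replication(
    s_track: BinnedTrack, g2_track: BinnedTrack, n: float
) -> ReplicationProfile:
    """Combine mean-normalized S and G2 tracks: R = S*(1+n) - G2 + 1."""
    if not s_track.compatible_with(g2_track):
        raise ValueError("S and G2 tracks differ in binning, chromosomes, or masks")
    if not 0 <= n <= 1:
        raise ValueError("replicated fraction n must be in [0, 1]")
    out = s_track.copy()
    for chrom in out.chroms:
        out.values[chrom] = s_track.values[chrom] * (1.0 + n) - g2_track.values[chrom] + 1.0
    return ReplicationProfile(R=out, provenance={"replicated_fraction_n": n})


def loess_smooth(
    track: BinnedTrack, span: float, window_bp: int | None = None
) -> BinnedTrack:
    """LOESS-smooth each chromosome over its unmasked bins.

    Degree-1 locally weighted regression with tricube weights (statsmodels
    ``lowess``), evaluated at every unmasked bin.  ``span`` is the fraction
    of unmasked bins in each local fit; alternatively ``window_bp`` fixes the
    local window in base pairs and the per-chromosome fraction is derived
    from it (convenient because the appropriate smoothing scale is physical,
    not a genome fraction).  A small ``delta`` keeps the cost roughly linear
    in track size: nearby fits are interpolated linearly, which is exact for
    locally linear signal and, at 2% of the local window, leaves peak apexes
    unquantized.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    out = track.copy()
    for chrom in out.chroms:
        keep = ~out.mask[chrom]
        x = np.flatnonzero(keep).astype(float)
        y = out.values[chrom][keep]
        if window_bp is not None:
            span = min(1.0, max(window_bp / track.step, 3) / max(len(y), 1))
        k = int(np.ceil(span * len(y)))
        if len(y) < max(3, k):
            raise ValueError(
                f"{chrom}: {len(y)} unmasked bins is fewer than the local window ({k})"
            )
        # interpolation distance: small enough (2% of the local window) that
        # peak apexes are not visibly quantized by the linear interpolation
        delta = max(1.0, 0.02 * k)
        sm = lowess(y, x, frac=span, it=0, delta=delta, return_sorted=False)
        if not np.all(np.isfinite(sm)):
            raise ValueError(f"{chrom}: LOESS produced non-finite values")
        out.values[chrom][keep] = sm
    return out


def build_profile(
    s_reads: pd.DataFrame,
    g2_reads: pd.DataFrame,
    chrom_lengths: dict[str, int],
    params: ProfileParams,
) -> ReplicationProfile:
    """Full construction: bin, mask, normalize, combine, smooth."""
    s_track = normalize_mean_one(bin_reads(s_reads, chrom_lengths, params))
    g2_track = normalize_mean_one(bin_reads(g2_reads, chrom_lengths, params))
    prof = combine_replication(s_track, g2_track, params.replicated_fraction_n)
    prof.R = loess_smooth(prof.R, params.loess_span, window_bp=params.loess_window_bp)
    prof.provenance.update(
        {
            "window": params.window,
            "step": params.step,
            "read_extension": params.read_extension,
            "loess_span": params.loess_span,
            "n_s_reads": int(len(s_reads)),
            "n_g2_reads": int(len(g2_reads)),
        }
    )
    return prof
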