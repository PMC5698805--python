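"""Identity-by-descent sharing profiles and sliding-window segment calling.

A marker is "shared" within a family when some founder haplotype label is
carried by every genotyped affected individual at that marker.  Segments
are called with a 10-SNP sliding window: a marker is IBD-positive when any
length-10 window covering it has strictly more than 50% shared markers
(>= 6 of 10), and maximal runs of positive markers become segments.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .pedigree import Pedigree


@dataclass
class SharingProfile:
    family_id: str
    chrom: str
    markers: list[int]              # strictly increasing positions
    shared: list[bool]

    def __post_init__(self):
        if len(self.markers) != len(self.shared):
            raise ValueError("markers and shared must have equal length")
        if any(b <= a for a, b in zip(self.markers, self.markers[1:])):
            raise ValueError("marker positions must be strictly increasing")


@dataclass
class IBDSegment:
    family_id: str
    chrom: str
    start_pos: int
    end_pos: int
    n_markers: int
    mean_sharing: float
    whole_chrom_fallback: bool = False

    def __post_init__(self):
        if self.start_pos > self.end_pos:
            raise ValueError("start_pos must be <= end_pos")


def sharing_profile(
    p: Pedigree,
    labels: dict[str, list[tuple[int, int]]],
    chrom: str,
    marker_positions: Sequence[int],
) -> SharingProfile:
    """Build the per-marker all-affecteds sharing profile for one family.

    ``labels[individual]`` holds the two founder-haplotype labels per
    marker (from the gene-dropping simulator or an external phasing step).
    Only genotyped affected individuals with labels enter the intersection.
    """
    affecteds = [m.id for m in p.affected() if m.genotyped and m.id in labels]
    if not affecteds:
        raise ValueError(f"family {p.family_id}: no genotyped affected individuals with labels")
    n = len(marker_positions)
    shared = []
    for i in range(n):
        common = set(labels[affecteds[0]][i])
        for ind in affecteds[1:]:
            common &= set(labels[ind][i])
            if not common:
                break
        shared.append(bool(common))
    return SharingProfile(p.family_id, chrom, list(marker_positions), shared)


def call_segments(
    sp: SharingProfile, window: int = 10, threshold: float = 0.5
) -> list[IBDSegment]:
    """Call IBD segments from a sharing profile via sliding windows.

    A marker is positive iff *any* covering window of ``window`` markers
    has a shared fraction strictly greater than ``threshold`` (max over
    windows, so 5/10 shared never passes the default rule).  With fewer
    markers than ``window`` the whole chromosome is evaluated as a single
    window and any resulting segment is flagged.
    """
    shared = np.asarray(sp.shared, dtype=bool)
    n = len(shared)
    if n == 0:
        return []
    fallback = n < window
    if fallback:
        # one whole-chromosome window; its verdict applies to every marker
        positive = np.full(n, shared.mean() > threshold)
    else:
        frac = np.convolve(shared.astype(float), np.ones(window), mode="valid") / window
        win_pass = frac > threshold          # window w covers markers [w, w+window)
        positive = np.zeros(n, dtype=bool)
        for w in np.nonzero(win_pass)[0]:
            positive[w : w + window] = True
    segments: list[IBDSegment] = []
    i = 0
    while i < n:
        if not positive[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and positive[j + 1]:
            j += 1
        segments.append(
            IBDSegment(
                family_id=sp.family_id,
                chrom=sp.chrom,
                start_pos=sp.markers[i],
                end_pos=sp.markers[j],
                n_markers=j - i + 1,
                mean_sharing=float(shared[i : j + 1].mean()),
                whole_chrom_fallback=fallback,
            )
        )
        i = j + 1
    return segments
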