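"""Genotype-, site-, sample- and marker-level quality filters, plus LD pruning.

Defaults reproduce the study's thresholds exactly: genotypes need depth >= 5
and GQ >= 20; sites need VQSLOD > 0 (strict), 35 bp mappability == 1 and
20 bp mappability >= 0.5; samples need call rate >= 0.98 and SNPs >= 0.95;
markers must be present in >= 60% of samples across platform batches; LD
pruning is greedy pairwise r^2 > 0.5 in 50-marker windows stepping by 5.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .variants import VariantAnnotation, VariantKey, VariantRecord


@dataclass
class QCConfig:
    min_depth: int = 5
    min_gq: int = 20
    min_vqslod: float = 0.0          # exclusive
    map35_required: float = 1.0      # equality
    map20_min: float = 0.5           # inclusive
    sample_call_rate_min: float = 0.98
    snp_call_rate_min: float = 0.95
    cross_platform_presence_min: float = 0.60
    ld_window: int = 50
    ld_step: int = 5
    ld_r2_max: float = 0.5

    def __post_init__(self):
        for name in ("sample_call_rate_min", "snp_call_rate_min", "cross_platform_presence_min"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.ld_window >= self.ld_step >= 1:
            raise ValueError("require ld_window >= ld_step >= 1")


def filter_genotypes(v: VariantRecord, cfg: QCConfig) -> VariantRecord:
    """Set calls failing depth or GQ thresholds to missing; keep the site.

    Boundaries are inclusive: depth 5 / GQ 20 pass under the defaults.
    """
    calls = {}
    for ind, call in v.calls.items():
        if call.is_missing or call.depth < cfg.min_depth or call.gq < cfg.min_gq:
            calls[ind] = call.as_missing()
        else:
            calls[ind] = call
    return replace(v, calls=calls)


def filter_sites(
    vs: Sequence[VariantRecord],
    annotations: dict[VariantKey, VariantAnnotation],
    cfg: QCConfig,
) -> list[VariantRecord]:
    """Keep sites passing VQSLOD (strict >) and mappability rules.

    A site without a VQSLOD value is retained (flag carried by the record's
    ``site_quality is None``); a site without annotation is retained since
    no mappability evidence argues against it.
    """
    kept = []
    for v in vs:
        if v.site_quality is not None and not (v.site_quality > cfg.min_vqslod):
            continue
        ann = annotations.get(v.key)
        if ann is not None:
            if ann.map35 != cfg.map35_required or ann.map20 < cfg.map20_min:
                continue
        kept.append(v)
    return kept


def sample_call_rates(vs: Sequence[VariantRecord]) -> dict[str, float]:
    """Per-sample fraction of non-missing calls across all sites."""
    if not vs:
        raise ValueError("no variants supplied")
    samples = sorted({s for v in vs for s in v.calls})
    if not samples:
        raise ValueError("no samples present")
    counts = {s: 0 for s in samples}
    for v in vs:
        for s in samples:
            call = v.calls.get(s)
            if call is not None and not call.is_missing:
                counts[s] += 1
    return {s: counts[s] / len(vs) for s in samples}


def snp_call_rate(v: VariantRecord) -> float:
    if not v.calls:
        raise ValueError("variant has no calls")
    present = sum(1 for c in v.calls.values() if not c.is_missing)
    return present / len(v.calls)


def batch_presence(
    call_present: dict[str, bool], batches: dict[str, str], min_fraction: float = 0.60
) -> bool:
    """Generic cross-platform presence rule: a marker passes iff it was
    attempted/present in at least ``min_fraction`` of all samples pooled
    across platform batches (``batches`` maps sample -> batch label and
    defines the sample universe)."""
    samples = list(batches)
    if not samples:
        raise ValueError("no samples in batch map")
    n_present = sum(1 for s in samples if call_present.get(s, False))
    return n_present / len(samples) >= min_fraction


def concordance(
    wes: dict[tuple[str, VariantKey], Optional[tuple[int, int]]],
    array: dict[tuple[str, VariantKey], Optional[tuple[int, int]]],
) -> float:
    """Fraction of shared non-missing (sample, site) pairs with identical
    unordered genotypes."""
    shared = [k for k in wes if k in array and wes[k] is not None and array[k] is not None]
    if not shared:
        raise ValueError("no overlapping non-missing (sample, site) pairs")
    same = sum(1 for k in shared if tuple(sorted(wes[k])) == tuple(sorted(array[k])))
    return same / len(shared)


# ----------------------------------------------------------------------
# LD pruning
# ----------------------------------------------------------------------
def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of dosages over complete pairs; 0 when
    fewer than 2 complete pairs or either marker is monomorphic there."""
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return 0.0
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def ld_prune(genotypes: np.ndarray, cfg: QCConfig) -> list[int]:
    """Greedy windowed LD pruning; returns kept marker indices (input order).

    ``genotypes`` is (n_markers, n_samples) dosage 0/1/2 with np.nan for
    missing, markers ordered by position.  Within each ``ld_window``-marker
    window, while any kept pair has r^2 > ``ld_r2_max``, one member of the
    worst pair is dropped — the one with the lower call rate, ties broken
    by dropping the later marker — then the window advances by ``ld_step``.
    """
    g = np.asarray(genotypes, dtype=float)
    n = g.shape[0]
    keep = np.ones(n, dtype=bool)
    call_rate = 1.0 - np.isnan(g).mean(axis=1)
    start = 0
    while start < n:
        idx = [i for i in range(start, min(start + cfg.ld_window, n)) if keep[i]]
        while True:
            worst = None
            for a_pos in range(len(idx)):
                for b_pos in range(a_pos + 1, len(idx)):
                    i, j = idx[a_pos], idx[b_pos]
                    r2 = _pairwise_r2(g[i], g[j])
                    if r2 > cfg.ld_r2_max and (worst is None or r2 > worst[0]):
                        worst = (r2, i, j)
            if worst is None:
                break
            _, i, j = worst
            if call_rate[i] < call_rate[j]:
                drop = i
            elif call_rate[j] < call_rate[i]:
                drop = j
            else:
                drop = max(i, j)  # later position
            keep[drop] = False
            idx.remove(drop)
        if start + cfg.ld_window >= n:
            break
        start += cfg.ld_step
    return [i for i in range(n) if keep[i]]
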