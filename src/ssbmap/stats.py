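"""The breakome statistics suite.

Interval enrichment with exact binomial tests, template-strand asymmetry,
replication-timing and signal-track comparisons, variant overlap in distance
windows, conservation profiles, per-base site profiles and normalized
scores, detection-sensitivity and library-complexity subsampling curves,
hotspot partitioning, and gene-set over-representation.

The enrichment odds ratio for k of n breaks in an element of length L_e on
a background of length L_bg is

    OR = (k / (n - k)) / (L_e / (L_bg - L_e)),

+inf when k = n, with a two-sided exact binomial p-value against
p0 = L_e / L_bg and a 95% CI obtained by transforming the Clopper-Pearson
interval on k/n to the odds-ratio scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from ._util import total_length
from .breakcall import BreakSet
from .tracks import SignalTrack

__all__ = [
    "EnrichmentResult",
    "StrandAsymmetry",
    "SiteProfile",
    "VariantSet",
    "element_enrichment",
    "strand_asymmetry",
    "replication_ratio",
    "track_compare",
    "variant_overlap",
    "conservation_profile",
    "site_profile",
    "normalized_site_score",
    "detection_sensitivity",
    "hotspots",
    "complexity_curve",
    "select_break_genes",
    "geneset_enrichment",
    "count_motif_sites",
]

Interval = tuple[str, int, int]


# --------------------------------------------------------------------------
# interval membership helpers

class _IntervalIndex:
    """Sorted, merged half-open intervals per chromosome with bisect lookup."""

    def __init__(self, intervals: Iterable[Interval]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv[0], []).append((iv[1], iv[2]))
        self._idx: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: list[tuple[int, int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            self._idx[chrom] = (np.array([s for s, _ in merged]),
                                np.array([e for _, e in merged]))

    def __contains__(self, point: tuple[str, int]) -> bool:
        chrom, pos = point
        se = self._idx.get(chrom)
        if se is None:
            return False
        starts, ends = se
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos < ends[i]


# --------------------------------------------------------------------------
# enrichment

@dataclass
class EnrichmentResult:
    k: int
    n: int
    element_length: int
    background_length: int
    odds_ratio: float
    p_value: float
    ci95: tuple[float, float]
    test: str = "binomial"

    @property
    def p0(self) -> float:
        return self.element_length / self.background_length


def _odds_ratio(k: int, n: int, L_e: int, L_bg: int) -> float:
    if k == n:
        return math.inf
    return (k / (n - k)) / (L_e / (L_bg - L_e))


def element_enrichment(
    breaks: BreakSet | Iterable[tuple[str, int]],
    element: Iterable[Interval],
    background: Iterable[Interval],
) -> EnrichmentResult:
    """Exact binomial enrichment of unique break coordinates in an element.

    Breaks outside the background are ignored; the element is intersected
    with the background for its length.  Overlap is half-open single-base
    membership, strand-blind.
    """
    element = list(element)
    background = list(background)
    L_bg = total_length(background)
    L_e = _intersect_length(element, background)
    if L_e == 0 or L_bg == L_e:
        raise ValueError(
            f"degenerate element length (L_e={L_e}, L_bg={L_bg}): odds ratio undefined"
        )
    eidx = _IntervalIndex(element)
    bidx = _IntervalIndex(background)
    positions = _break_positions(breaks)
    n = k = 0
    for chrom, pos in positions:
        if (chrom, pos) in bidx:
            n += 1
            if (chrom, pos) in eidx:
                k += 1
    if n < 1:
        raise ValueError("no breaks in the background")
    p0 = L_e / L_bg
    p = sps.binomtest(k, n, p0, alternative="two-sided").pvalue
    lo, hi = sps.beta.ppf(0.025, k, n - k + 1) if k > 0 else 0.0, \
        sps.beta.ppf(0.975, k + 1, n - k) if k < n else 1.0
    odds0 = L_e / (L_bg - L_e)
    ci = (
        (lo / (1 - lo)) / odds0 if lo < 1 else math.inf,
        (hi / (1 - hi)) / odds0 if hi < 1 else math.inf,
    )
    return EnrichmentResult(k, n, L_e, L_bg, _odds_ratio(k, n, L_e, L_bg), p, ci)


def _intersect_length(element: list[Interval], background: list[Interval]) -> int:
    pieces = []
    for ec, es, ee in ((iv[0], iv[1], iv[2]) for iv in element):
        for bc, bs, be in ((iv[0], iv[1], iv[2]) for iv in background):
            if ec == bc and es < be and bs < ee:
                pieces.append((ec, max(es, bs), min(ee, be)))
    return total_length(pieces) if pieces else 0


def _break_positions(breaks) -> list[tuple[str, int]]:
    if isinstance(breaks, BreakSet):
        return [(c, p) for c, p, _ in breaks.calls]
    return [(b[0], b[1]) for b in breaks]


# --------------------------------------------------------------------------
# strand asymmetry

@dataclass
class StrandAsymmetry:
    template_count: int
    nontemplate_count: int

    @property
    def ratio(self) -> float:
        if self.nontemplate_count == 0:
            raise ZeroDivisionError("non-template count is zero; ratio undefined")
        return self.template_count / self.nontemplate_count


def strand_asymmetry(
    breaks: BreakSet,
    regions: Iterable[tuple[str, int, int, str, str]],
    count_both_strand_regions: bool = False,
) -> dict[str, StrandAsymmetry]:
    """Template / non-template break counts per region class.

    ``regions`` are (chrom, start, end, gene_strand, class) with class
    typically ``exon`` or ``intron``.  A break inside a region of a '+'
    gene is a template-strand break iff the broken strand is '-' (the
    template is the strand complementary to the sense/mRNA-like strand),
    and mirrored for '-' genes.  Bases annotated with genes on both
    strands are excluded unless ``count_both_strand_regions``.
    """
    regs = list(regions)
    out: dict[str, StrandAsymmetry] = {}
    classes = sorted({r[4] for r in regs})
    for klass in classes:
        out[klass] = StrandAsymmetry(0, 0)
    for chrom, pos, strand in breaks.calls:
        for klass in classes:
            gene_strands = {
                r[3] for r in regs
                if r[4] == klass and r[0] == chrom and r[1] <= pos < r[2]
            }
            if not gene_strands:
                continue
            if len(gene_strands) > 1 and not count_both_strand_regions:
                continue
            for gs in gene_strands:
                template = strand != gs
                if template:
                    out[klass].template_count += 1
                else:
                    out[klass].nontemplate_count += 1
                if not count_both_strand_regions:
                    break
    return out


# --------------------------------------------------------------------------
# signal tracks

def replication_ratio(
    breaks: BreakSet,
    fraction_tracks: Mapping[str, SignalTrack],
    background: Iterable[Interval] | None = None,
) -> dict[str, float]:
    """Per-cell-cycle-fraction enrichment (>1) or depletion (<1) of breaks.

    ratio(fraction) = mean track value at break positions divided by the
    length-weighted mean track value over the background.
    """
    positions = [(c, p) for c, p, _ in breaks.calls]
    background = list(background) if background is not None else None
    out = {}
    for name, track in fraction_tracks.items():
        bg_mean = track.mean(background)
        if bg_mean == 0 or np.isnan(bg_mean):
            raise ValueError(f"background mean for fraction {name} is zero/undefined")
        vals = track.values_at(positions)
        out[name] = float(np.nanmean(vals)) / bg_mean
    return out


def track_compare(
    breaks: BreakSet,
    track: SignalTrack,
    n_background: int = 10_000,
    seed: int = 0,
    method: str = "auto",
    background_positions: Sequence[tuple[str, int]] | None = None,
) -> dict:
    """Track values at breaks vs a background sample of positions.

    The background is ``n_background`` positions sampled uniformly over
    the track (seeded), or the explicit ``background_positions`` when
    given.  Two-sided Wilcoxon rank-sum (Mann-Whitney U); ``method``
    'exact' forces the exact null distribution (valid without ties),
    'auto' defers to scipy's choice.
    """
    break_vals = track.values_at([(c, p) for c, p, _ in breaks.calls])
    break_vals = break_vals[~np.isnan(break_vals)]
    if len(break_vals) == 0:
        raise ValueError("no break positions covered by the track")
    if background_positions is not None:
        bg_vals = track.values_at(background_positions)
    else:
        if n_background < 10:
            raise ValueError("n_background must be >= 10")
        rng = np.random.default_rng(seed)
        chroms = [c for c, arr in track.values.items() if len(arr)]
        lengths = np.array([len(track.values[c]) for c in chroms], dtype=float)
        picks = rng.choice(len(chroms), size=n_background,
                           p=lengths / lengths.sum())
        bg_vals = np.array([
            track.values[chroms[i]][rng.integers(len(track.values[chroms[i]]))]
            for i in picks
        ])
    bg_vals = bg_vals[~np.isnan(bg_vals)]
    res = sps.mannwhitneyu(break_vals, bg_vals, alternative="two-sided",
                           method=method)
    return {
        "median_breaks": float(np.median(break_vals)),
        "median_background": float(np.median(bg_vals)),
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "n_breaks": int(len(break_vals)),
        "n_background": int(len(bg_vals)),
    }


# --------------------------------------------------------------------------
# variants

@dataclass
class VariantSet:
    """Variant records with allele-frequency classes.

    Class thresholds follow common population-genetics convention:
    common AF >= 0.05, low_frequency 0.005 <= AF < 0.05, rare AF < 0.005.
    """

    records: list[tuple[str, int, str, float]] = field(default_factory=list)

    COMMON_AF = 0.05
    LOW_AF = 0.005

    @staticmethod
    def af_class(af: float) -> str:
        if af >= VariantSet.COMMON_AF:
            return "common"
        if af >= VariantSet.LOW_AF:
            return "low_frequency"
        return "rare"

    def positions(self, vtype: str, af_class: str) -> list[tuple[str, int]]:
        return [
            (c, p) for c, p, t, af in self.records
            if t == vtype and not math.isnan(af) and self.af_class(af) == af_class
        ]


def variant_overlap(
    breaks: BreakSet,
    variants: VariantSet,
    background_length: int,
    windows: Sequence[int] = (0, 2, 5, 10),
    types: Sequence[str] = ("SNP", "indel"),
    classes: Sequence[str] = ("common", "low_frequency", "rare"),
) -> dict[tuple[str, str, int], EnrichmentResult]:
    """Break-variant proximity enrichment per (type, AF class, window).

    A break hits a variant iff |break_pos - variant_pos| <= w (strand
    blind).  Under uniform variant density rho = m / L_bg the null hit
    probability is 1 - (1 - rho)^(2w+1); hits are tested with a two-sided
    exact binomial.
    """
    positions = [(c, p) for c, p, _ in breaks.calls]
    n = len(positions)
    if n == 0:
        raise ValueError("empty break set")
    out: dict[tuple[str, str, int], EnrichmentResult] = {}
    for vtype in types:
        for klass in classes:
            vpos = variants.positions(vtype, klass)
            by_chrom: dict[str, np.ndarray] = {}
            for c, p in vpos:
                by_chrom.setdefault(c, []).append(p)  # type: ignore[arg-type]
            by_chrom = {c: np.sort(np.array(v)) for c, v in by_chrom.items()}
            m = len(vpos)
            rho = m / background_length
            for w in windows:
                k = 0
                for c, p in positions:
                    arr = by_chrom.get(c)
                    if arr is None or len(arr) == 0:
                        continue
                    i = int(np.searchsorted(arr, p))
                    near = min(
                        abs(int(arr[j]) - p)
                        for j in (i - 1, i) if 0 <= j < len(arr)
                    )
                    if near <= w:
                        k += 1
                p0 = 1.0 - (1.0 - rho) ** (2 * w + 1)
                if p0 <= 0.0 or p0 >= 1.0:
                    pval, ci = 1.0, (0.0, math.inf)
                    odds = math.nan
                else:
                    pval = sps.binomtest(k, n, p0, alternative="two-sided").pvalue
                    odds0 = p0 / (1 - p0)
                    odds = math.inf if k == n else (k / (n - k)) / odds0
                    lo = sps.beta.ppf(0.025, k, n - k + 1) if k > 0 else 0.0
                    hi = sps.beta.ppf(0.975, k + 1, n - k) if k < n else 1.0
                    ci = (
                        (lo / (1 - lo)) / odds0 if lo < 1 else math.inf,
                        (hi / (1 - hi)) / odds0 if hi < 1 else math.inf,
                    )
                out[(vtype, klass, w)] = EnrichmentResult(
                    k, n, 2 * w + 1, background_length, odds, pval, ci,
                    test="binomial(proximity)",
                )
    return out


# --------------------------------------------------------------------------
# conservation

def conservation_profile(
    breaks: BreakSet,
    score_track: SignalTrack,
    windows: Sequence[int] = (5, 10, 20),
) -> dict[int, dict[str, float]]:
    """Windowed conservation summaries around breaks.

    Per break and window +/-w: the mean over strictly positive scores, the
    mean absolute value over strictly negative scores (same-sign-only
    averaging), and the ratio of the window mean to the score at the break
    base.  Sample-level values are means over breaks; breaks with no track
    coverage are excluded and counted.
    """
    out: dict[int, dict[str, float]] = {}
    for w in windows:
        pos_means, neg_means, ratios = [], [], []
        excluded = 0
        for chrom, pos, _ in breaks.calls:
            vals = score_track.window_values(chrom, pos, w)
            vals = vals[~np.isnan(vals)]
            if len(vals) == 0:
                excluded += 1
                continue
            pv = vals[vals > 0]
            nv = vals[vals < 0]
            pos_means.append(pv.mean() if len(pv) else 0.0)
            neg_means.append(np.abs(nv).mean() if len(nv) else 0.0)
            at_break = score_track.value_at(chrom, pos)
            if not math.isnan(at_break) and at_break != 0:
                ratios.append(float(vals.mean()) / at_break)
        out[w] = {
            "mean_positive": float(np.mean(pos_means)) if pos_means else math.nan,
            "mean_negative_abs": float(np.mean(neg_means)) if neg_means else math.nan,
            "nearby_over_break_ratio": float(np.mean(ratios)) if ratios else math.nan,
            "n_excluded": excluded,
        }
    return out


# --------------------------------------------------------------------------
# site profiles and scores

@dataclass
class SiteProfile:
    """Fraction of a sample's SSBs at each site-relative offset and strand.

    ``fractions[(offset, strand)]`` where offset 0 is the first site base
    (offsets negative upstream, running to site length - 1 + flank) and
    strand 'top'/'bottom' is relative to the site orientation.  Fractions
    are of the sample's total breaks, so they sum to <= 1.
    """

    fractions: dict[tuple[int, str], float]
    flank: int
    site_length: int
    total_breaks: int

    def total(self) -> float:
        return sum(self.fractions.values())

    def argmax(self) -> tuple[int, str]:
        return max(self.fractions, key=lambda k: self.fractions[k])


def site_profile(
    breaks: BreakSet,
    sites: Iterable[tuple[str, int, int, str]],
    flank: int = 10,
) -> SiteProfile:
    """Aggregate per-base break fractions across motif sites.

    Sites are (chrom, start, end, strand) motif occurrences; minus-strand
    occurrences are coordinate-flipped so offsets are motif-relative and
    the 'top' strand is the motif-bearing strand.
    """
    sites = list(sites)
    if not sites:
        raise ValueError("no sites")
    site_len = sites[0][2] - sites[0][1]
    counts: dict[tuple[int, str], int] = {}
    total = len(breaks)
    if total == 0:
        raise ValueError("empty break set")
    by_key = breaks.calls
    for chrom, start, end, sstrand in sites:
        for off in range(-flank, (end - start) + flank):
            if sstrand == "+":
                gpos = start + off
                for bstrand, rel in (("+", "top"), ("-", "bottom")):
                    if (chrom, gpos, bstrand) in by_key:
                        counts[(off, rel)] = counts.get((off, rel), 0) + 1
            else:
                gpos = end - 1 - off
                for bstrand, rel in (("-", "top"), ("+", "bottom")):
                    if (chrom, gpos, bstrand) in by_key:
                        counts[(off, rel)] = counts.get((off, rel), 0) + 1
    fractions = {k: v / total for k, v in counts.items()}
    return SiteProfile(fractions, flank, site_len, total)


def normalized_site_score(
    breaks: BreakSet,
    positions: Iterable[tuple[str, int]],
) -> dict[tuple[str, int], float]:
    """score(position) = SSBs detected at the position * 1e9 / total SSBs.

    Counts are unique break coordinates (a position carrying breaks on both
    strands counts 2), so summed over the whole genome the scores conserve:
    sum(scores) * total / 1e9 = total.
    """
    total = len(breaks)
    if total == 0:
        raise ValueError("empty break set")
    per_pos: dict[tuple[str, int], int] = {}
    for chrom, pos, _ in breaks.calls:
        per_pos[(chrom, pos)] = per_pos.get((chrom, pos), 0) + 1
    return {
        (c, p): per_pos.get((c, p), 0) * 1e9 / total
        for c, p in positions
    }


# --------------------------------------------------------------------------
# subsampling curves

def detection_sensitivity(
    read_calls: Sequence,
    sites: Sequence[tuple[str, int]],
    depths: Sequence[int],
    seed: int = 0,
    window: int = 1,
) -> list[float]:
    """Fraction of sites detected at each subsampled read depth.

    ``read_calls`` are read-level SSB calls (or (chrom, pos, strand)
    tuples); a site is detected when >= 1 surviving call lies within
    +/-``window`` of its position.  Subsampling is without replacement,
    seeded.
    """
    rng = np.random.default_rng(seed)
    positions = _call_tuples(read_calls)
    n = len(positions)
    out = []
    site_arr: dict[str, np.ndarray] = {}
    for c, p in sites:
        site_arr.setdefault(c, []).append(p)  # type: ignore[arg-type]
    site_arr = {c: np.sort(np.array(v)) for c, v in site_arr.items()}
    for d in depths:
        if d > n:
            raise ValueError(f"depth {d} exceeds available reads {n}")
        idx = rng.choice(n, size=d, replace=False)
        detected: set[tuple[str, int]] = set()
        for i in idx:
            chrom, pos, _ = positions[i]
            arr = site_arr.get(chrom)
            if arr is None:
                continue
            j = int(np.searchsorted(arr, pos))
            for jj in (j - 1, j):
                if 0 <= jj < len(arr) and abs(int(arr[jj]) - pos) <= window:
                    detected.add((chrom, int(arr[jj])))
        out.append(len(detected) / len(sites))
    return out


def hotspots(
    breaks: BreakSet, min_reads: int = 4
) -> tuple[BreakSet, BreakSet]:
    """Partition unique positions into hotspots (read_count >= min_reads)
    and the rest.  Hotspot analysis is the one place read counts are kept
    instead of collapsing to unique coordinates."""
    hot = BreakSet(sample_id=breaks.sample_id,
                   provenance=breaks.provenance + [f"hotspots(min_reads={min_reads})"])
    rest = BreakSet(sample_id=breaks.sample_id,
                    provenance=breaks.provenance + [f"hotspots(rest<{min_reads})"])
    for key, call in breaks.calls.items():
        (hot if call.read_count >= min_reads else rest).calls[key] = call
    hot.total_filtered_reads = sum(c.read_count for c in hot.calls.values())
    rest.total_filtered_reads = sum(c.read_count for c in rest.calls.values())
    return hot, rest


def complexity_curve(
    read_calls: Sequence,
    depths: Sequence[int],
    seed: int = 0,
) -> list[float]:
    """Unique-coordinate / total-read ratio at each subsampled depth
    (library complexity; decreasing with depth as positions saturate)."""
    rng = np.random.default_rng(seed)
    positions = _call_tuples(read_calls)
    n = len(positions)
    out = []
    for d in depths:
        if d > n or d < 1:
            raise ValueError(f"bad depth {d} for {n} reads")
        idx = rng.choice(n, size=d, replace=False)
        uniq = {positions[i] for i in idx}
        out.append(len(uniq) / d)
    return out


def _call_tuples(read_calls: Sequence) -> list[tuple[str, int, str]]:
    out = []
    for c in read_calls:
        if hasattr(c, "key"):
            out.append(c.key)
        else:
            out.append((c[0], c[1], c[2]))
    return out


# --------------------------------------------------------------------------
# gene selection and gene sets

def select_break_genes(
    breaks: BreakSet,
    genes: Sequence[tuple[str, int, int, str, str]],
    promoters: Sequence[Interval] | None = None,
    exons: Mapping[str, Sequence[Interval]] | None = None,
    region: str = "promoter",
    min_breaks: int = 3,
    max_distance: int = 5000,
    exon_universe: str = "assigned",
) -> tuple[list[str], list[str]]:
    """Genes with >= ``min_breaks`` unique breaks in promoters or exons.

    Promoter mode: each promoter is assigned to the gene whose annotated 5'
    end is nearest, provided the promoter interval lies within
    ``max_distance`` of it (ties broken by gene name, deterministically);
    the universe is the set of promoter-assigned genes.  Exon mode counts
    breaks in each gene's exons; the universe is assigned genes or all
    genes per ``exon_universe``.
    """
    genes = list(genes)
    if region == "promoter":
        if promoters is None:
            raise ValueError("promoter mode requires promoters")
        assigned: dict[str, list[Interval]] = {}
        for prom in promoters:
            pc, ps, pe = prom[0], prom[1], prom[2]
            best: tuple[int, str] | None = None
            for gc, gs, ge, gstrand, gname in genes:
                if gc != pc:
                    continue
                tss = gs if gstrand == "+" else ge - 1
                if ps <= tss < pe:
                    dist = 0
                else:
                    dist = min(abs(tss - ps), abs(tss - (pe - 1)))
                if dist <= max_distance and (best is None or (dist, gname) < best):
                    best = (dist, gname)
            if best is not None:
                assigned.setdefault(best[1], []).append((pc, ps, pe))
        universe = sorted(assigned)
        selected = [
            g for g in universe
            if _count_breaks_in(breaks, assigned[g]) >= min_breaks
        ]
        return selected, universe
    if region == "exon":
        if exons is None:
            raise ValueError("exon mode requires exons")
        universe = sorted(exons) if exon_universe == "assigned" else \
            sorted({g[4] for g in genes})
        selected = [
            g for g in sorted(exons)
            if _count_breaks_in(breaks, exons[g]) >= min_breaks
        ]
        return selected, universe
    raise ValueError(f"unknown region {region!r}")


def _count_breaks_in(breaks: BreakSet, intervals: Sequence[Interval]) -> int:
    idx = _IntervalIndex(intervals)
    return sum(1 for c, p, _ in breaks.calls if (c, p) in idx)


def geneset_enrichment(
    selected: Sequence[str],
    universe: Sequence[str],
    sets: Mapping[str, Sequence[str]],
) -> list[dict]:
    """One-sided hypergeometric over-representation per gene set, with
    Benjamini-Hochberg adjustment across sets.

    The 2x2 table for a set of size K in a universe of size N with n
    selected genes and k of them in the set gives OR = (k (N-K-n+k)) /
    ((n-k)(K-k)).
    """
    uni = set(universe)
    sel = set(selected) & uni
    if not sel <= uni:
        raise ValueError("selected genes must be a subset of the universe")
    N, n = len(uni), len(sel)
    rows = []
    for name in sorted(sets):
        members = set(sets[name]) & uni
        K = len(members)
        if K == 0:
            continue
        k = len(sel & members)
        p = float(sps.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        a, b, c, d = k, n - k, K - k, N - K - (n - k)
        odds = math.inf if b * c == 0 and a * d > 0 else (
            math.nan if b * c == 0 else (a * d) / (b * c))
        rows.append({"set": name, "k": k, "K": K, "n": n, "N": N,
                     "odds_ratio": odds, "p_value": p})
    if rows:
        adj = multipletests([r["p_value"] for r in rows], method="fdr_bh")[1]
        for r, q in zip(rows, adj):
            r["p_adjusted"] = float(q)
    return rows


# --------------------------------------------------------------------------
# motif scanning

def count_motif_sites(
    sequences: Mapping[str, str], motif: str, both_strands: bool = False
) -> list[tuple[str, int, int, str]]:
    """All (possibly overlapping) motif occurrences as BED-like intervals.

    For palindromic motifs plus-strand scanning already reports every site
    once; ``both_strands`` additionally scans the reverse complement.
    """
    from ._util import revcomp

    out = []
    targets = [(motif, "+")]
    if both_strands and revcomp(motif) != motif:
        targets.append((revcomp(motif), "-"))
    for chrom, seq in sequences.items():
        for sub, strand in targets:
            i = seq.find(sub)
            while i != -1:
                out.append((chrom, i, i + len(sub), strand))
                i = seq.find(sub, i + 1)
    out.sort()
    return out
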