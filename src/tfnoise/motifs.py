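"""Motif scanning with mismatch tolerance and TF-binding promoter features.

Promoters span −1000..+10 relative to the start codon (1010 bp); internal
coordinates are 0-based, half-open, on the forward strand, with
`tfnoise.synthetic.signed_position` converting to the signed biologist
convention. The scanner reports every window on either strand whose Hamming
distance to the nearest consensus variant is at most `max_mismatch`
(default 2). Because variant sets expanded from a weight matrix or IUPAC
consensus are products of per-position base sets, the minimal Hamming
distance over all variants equals the count of positions whose base is not
allowed — the scan is exact without enumerating variants.

Feature extraction covers binding-site overlaps (competition), positional
site counts in 100-bp windows, nucleosome-occupancy window averages, the
tRNA adaptation index over codon prefixes, and the mismatch degeneracy of
overlapping versus non-overlapping sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd

from tfnoise.synthetic import reverse_complement, signed_position

__all__ = [
    "Motif",
    "MotifSite",
    "OverlapStats",
    "scan_motif",
    "scan_promoters",
    "count_overlaps",
    "positional_site_counts",
    "occupancy_windows",
    "OCCUPANCY_WINDOWS",
    "tai",
    "overlap_degeneracy",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
MAX_VARIANTS = 10**6


@dataclass
class Motif:
    """A TF binding motif as per-position allowed-base sets.

    `allowed` is a (length, 4) boolean matrix over the base order ACGT; a
    window matches a variant exactly iff every position holds an allowed
    base, so Hamming distance to the nearest variant is the number of
    disallowed positions.
    """

    tf_id: str
    allowed: np.ndarray
    consensus: str = ""

    def __post_init__(self) -> None:
        self.allowed = np.asarray(self.allowed, dtype=bool)
        if self.allowed.ndim != 2 or self.allowed.shape[1] != 4:
            raise ValueError("allowed must be (length, 4)")
        if not self.allowed.any(axis=1).all():
            raise ValueError("every motif position needs at least one allowed base")
        if not self.consensus:
            self.consensus = "".join(
                "ACGT"[row.argmax()] for row in self.allowed
            )

    def __len__(self) -> int:
        return self.allowed.shape[0]

    @classmethod
    def from_consensus(cls, tf_id: str, consensus: str) -> "Motif":
        """Build from an exact or IUPAC-degenerate consensus string."""
        consensus = consensus.upper()
        allowed = np.zeros((len(consensus), 4), dtype=bool)
        for i, ch in enumerate(consensus):
            if ch not in IUPAC:
                raise ValueError(f"invalid IUPAC code {ch!r} in consensus")
            for b in IUPAC[ch]:
                allowed[i, _BASE_INDEX[b]] = True
        return cls(tf_id=tf_id, allowed=allowed, consensus=consensus)

    @classmethod
    def from_pwm(
        cls, tf_id: str, matrix: np.ndarray, threshold_fraction: float = 0.0
    ) -> "Motif":
        """Build from a (length, 4) weight matrix.

        A base is allowed at a position when its weight exceeds
        `threshold_fraction` of the position's maximum weight (default: any
        base with nonzero weight, i.e. all possible base combinations).
        """
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[1] != 4:
            raise ValueError("weight matrix must be (length, 4) over ACGT")
        cutoff = threshold_fraction * matrix.max(axis=1, keepdims=True)
        allowed = matrix > np.maximum(cutoff, 0.0) if threshold_fraction > 0 else matrix > 0
        motif = cls(tf_id=tf_id, allowed=allowed)
        if motif.n_variants > MAX_VARIANTS:
            raise ValueError(
                f"motif expands to {motif.n_variants:.3g} variants (> {MAX_VARIANTS:g}); "
                "raise threshold_fraction to restrict per-position bases"
            )
        return motif

    @property
    def n_variants(self) -> int:
        return int(np.prod(self.allowed.sum(axis=1)))

    def variants(self) -> list[str]:
        """Enumerate all consensus variants (guarded against explosion)."""
        if self.n_variants > MAX_VARIANTS:
            raise ValueError("variant expansion too large; use the allowed matrix")
        per_pos = ["".join(b for b in "ACGT" if row[_BASE_INDEX[b]]) for row in self.allowed]
        return ["".join(combo) for combo in product(*per_pos)]

    def reverse_complement(self) -> "Motif":
        return Motif(
            tf_id=self.tf_id,
            allowed=self.allowed[::-1, ::-1],
            consensus=reverse_complement(self.consensus) if set(self.consensus) <= set("ACGT") else "",
        )


@dataclass(frozen=True)
class MotifSite:
    """A located binding site (promoter-local, 0-based, half-open)."""

    promoter_id: str
    tf_id: str
    start: int
    end: int
    strand: str
    n_mismatches: int
    matched_variant: str = ""


def _encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3; anything else -> 4 (mismatches every base)."""
    table = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    codes = table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 4).any():
        warnings.warn("non-ACGT characters in sequence treated as universal mismatches")
    return codes


def _scan_one_strand(codes: np.ndarray, motif: Motif, max_mismatch: int) -> tuple[np.ndarray, np.ndarray]:
    length = len(motif)
    if len(codes) < length:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(codes, length)
    allowed = np.hstack([motif.allowed, np.zeros((length, 1), dtype=bool)])  # column for code 4
    ok = allowed[np.arange(length)[None, :], windows]
    mismatches = length - ok.sum(axis=1)
    hits = np.nonzero(mismatches <= max_mismatch)[0]
    return hits, mismatches[hits]


def _nearest_variant(window: str, motif: Motif) -> str:
    out = []
    for i, ch in enumerate(window):
        idx = _BASE_INDEX.get(ch.upper())
        if idx is not None and motif.allowed[i, idx]:
            out.append(ch.upper())
        else:
            out.append("ACGT"[motif.allowed[i].argmax()])
    return "".join(out)


def scan_motif(
    sequence: str,
    motif: Motif,
    max_mismatch: int = 2,
    both_strands: bool = True,
    promoter_id: str = "",
) -> list[MotifSite]:
    """All motif sites with at most `max_mismatch` mismatches, sorted by start.

    Both the forward sequence and its reverse complement are scanned by
    default; palindromic double hits covering the same interval are reported
    once, keeping the forward-strand call.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    if len(sequence) < len(motif):
        raise ValueError("promoter shorter than motif")
    codes = _encode(sequence)
    n = len(sequence)
    length = len(motif)
    sites: dict[tuple[int, int], MotifSite] = {}
    starts, mms = _scan_one_strand(codes, motif, max_mismatch)
    for s, mm in zip(starts, mms):
        window = sequence[s : s + length].upper()
        sites[(s, s + length)] = MotifSite(
            promoter_id, motif.tf_id, int(s), int(s + length), "+", int(mm),
            _nearest_variant(window, motif),
        )
    if both_strands:
        rc_motif = motif.reverse_complement()
        starts, mms = _scan_one_strand(codes, rc_motif, max_mismatch)
        for s, mm in zip(starts, mms):
            key = (int(s), int(s + length))
            if key in sites and sites[key].n_mismatches <= mm:
                continue  # palindromic double hit: minimal distance wins, ties keep +
            window = sequence[s : s + length].upper()
            variant = _nearest_variant(window, rc_motif)
            sites[key] = MotifSite(
                promoter_id, motif.tf_id, key[0], key[1], "-", int(mm),
                reverse_complement(variant) if set(variant) <= set("ACGT") else variant,
            )
    return sorted(sites.values(), key=lambda s: (s.start, s.end, s.strand))


def scan_promoters(
    promoters: dict[str, str],
    motifs: list[Motif],
    max_mismatch: int = 2,
    both_strands: bool = True,
) -> pd.DataFrame:
    """Scan every motif against every promoter; BED-compatible table."""
    rows = []
    for name, seq in promoters.items():
        for motif in motifs:
            for site in scan_motif(seq, motif, max_mismatch, both_strands, name):
                rows.append(
                    {
                        "chrom": site.promoter_id,
                        "start": site.start,
                        "end": site.end,
                        "name": site.tf_id,
                        "score": site.n_mismatches,
                        "strand": site.strand,
                        "signed_start": signed_position(site.start, len(seq)),
                        "matched_variant": site.matched_variant,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "name", "score", "strand",
            "signed_start", "matched_variant",
        ],
    )


# ---------------------------------------------------------------------------
# overlap features
# ---------------------------------------------------------------------------


@dataclass
class OverlapStats:
    """Pairwise overlap summary of the binding sites on one promoter."""

    n_sites: int
    n_overlapping_pairs: int
    overlaps_per_site: float  # overlapping pairs / total sites
    frac_sites_overlapping: float  # sites participating in >=1 overlap / total
    mean_overlap_length: float  # bp, NaN when no pairs
    per_window_pair_counts: dict = field(default_factory=dict)
    pair_category_fractions: dict = field(default_factory=dict)


def count_overlaps(
    sites: list[MotifSite],
    windows: list[tuple[int, int]] | None = None,
    role_map: dict[str, str] | None = None,
    exclude_same_tf: bool = False,
) -> OverlapStats:
    """Pairwise interval-overlap statistics (strand-agnostic).

    Two sites overlap iff their intervals share at least one bp. Each
    overlapping pair is attributed to the window containing the midpoint of
    its overlap; with a TF role map the pairs are classified as
    activator–activator, repressor–repressor or activator–repressor.
    """
    n = len(sites)
    pairs = []
    involved: set[int] = set()
    for i, j in combinations(range(n), 2):
        if exclude_same_tf and sites[i].tf_id == sites[j].tf_id:
            continue
        lo = max(sites[i].start, sites[j].start)
        hi = min(sites[i].end, sites[j].end)
        if hi > lo:
            pairs.append((i, j, lo, hi))
            involved.update((i, j))
    per_window: dict = {}
    if windows is not None:
        per_window = {w: 0 for w in windows}
        for _, _, lo, hi in pairs:
            mid = (lo + hi) / 2.0
            for w in windows:
                if w[0] <= mid < w[1]:
                    per_window[w] += 1
                    break
    categories: dict = {}
    if role_map is not None and pairs:
        counts = {"activator-activator": 0, "repressor-repressor": 0, "activator-repressor": 0}
        classified = 0
        for i, j, *_ in pairs:
            ri = role_map.get(sites[i].tf_id)
            rj = role_map.get(sites[j].tf_id)
            if ri not in ("activator", "repressor") or rj not in ("activator", "repressor"):
                continue
            classified += 1
            if ri == rj:
                counts[f"{ri}-{ri}"] += 1
            else:
                counts["activator-repressor"] += 1
        categories = {
            k: (v / classified if classified else np.nan) for k, v in counts.items()
        }
    return OverlapStats(
        n_sites=n,
        n_overlapping_pairs=len(pairs),
        overlaps_per_site=len(pairs) / n if n else 0.0,
        frac_sites_overlapping=len(involved) / n if n else 0.0,
        mean_overlap_length=float(np.mean([hi - lo for *_, lo, hi in pairs])) if pairs else np.nan,
        per_window_pair_counts=per_window,
        pair_category_fractions=categories,
    )


def positional_site_counts(
    sites: list[MotifSite],
    promoter_length: int = 1010,
    window_size: int = 100,
) -> pd.Series:
    """Site counts per upstream distance window, attributed by site start.

    Windows are `window_size`-bp bands upstream of the start codon
    ("0-100bp upstream", "100-200bp upstream", ...) plus a "downstream"
    band for the −0..+10 tail beyond the start codon. Counts sum to the
    number of sites.
    """
    codon_start = promoter_length - 10
    n_windows = int(np.ceil(codon_start / window_size))
    labels = [f"{i * window_size}-{(i + 1) * window_size}bp upstream" for i in range(n_windows)]
    counts = {label: 0 for label in labels}
    counts["downstream"] = 0
    for site in sites:
        if site.start >= codon_start:
            counts["downstream"] += 1
        else:
            upstream = codon_start - site.start  # bp upstream of the start codon
            idx = min((upstream - 1) // window_size, n_windows - 1)
            counts[labels[idx]] += 1
    return pd.Series(counts, name="n_sites")


#: Nucleosome-occupancy averaging windows in signed promoter coordinates:
#: 100-bp bands from −1000 to −200, then 50-bp bands, then −50..+10.
OCCUPANCY_WINDOWS: tuple[tuple[int, int], ...] = tuple(
    [(-1000 + 100 * i, -900 + 100 * i) for i in range(8)]
    + [(-200, -150), (-150, -100), (-100, -50), (-50, 10)]
)


def occupancy_windows(
    positions: np.ndarray,
    values: np.ndarray,
    windows: tuple[tuple[int, int], ...] = OCCUPANCY_WINDOWS,
    occupied_threshold: float = 0.0,
) -> pd.Series:
    """Mean occupancy per promoter window ("per occupied site").

    `positions` are signed promoter coordinates (no position 0); the average
    in each [lo, hi) window runs over covered positions with occupancy above
    `occupied_threshold` (at the default 0 every covered position counts, a
    plain mean). Positions missing from the track are excluded with a
    warning; a window with no contributing positions is NaN.
    """
    positions = np.asarray(positions)
    values = np.asarray(values, dtype=float)
    out = {}
    expected = sum(hi - lo for lo, hi in windows)
    covered = 0
    for lo, hi in windows:
        mask = (positions >= lo) & (positions < hi)
        covered += int(mask.sum())
        vals = values[mask]
        if occupied_threshold > 0:
            vals = vals[vals > occupied_threshold]
        out[f"{lo}:{hi}"] = float(vals.mean()) if len(vals) else np.nan
    if covered < expected - len(windows):  # tolerate the missing "position 0" per window
        warnings.warn(
            f"occupancy track covers {covered} of ~{expected} window positions; "
            "missing positions excluded from averages"
        )
    return pd.Series(out, name="mean_occupancy")


# ---------------------------------------------------------------------------
# tRNA adaptation index
# ---------------------------------------------------------------------------

_STOP_CODONS = {"TAA", "TAG", "TGA"}
TAI_PREFIXES = (5, 10, 15, 20, 25, 30, 40, 50, None)  # None = full gene


def tai(
    coding_sequence: str,
    codon_weights: dict[str, float],
    prefix_lengths: tuple[int | None, ...] = TAI_PREFIXES,
) -> pd.DataFrame:
    """tRNA adaptation index: geometric mean of codon weights per prefix.

    Stop codons inside a prefix are excluded from the geometric mean (with a
    warning); a prefix longer than the gene returns the full-gene value with
    the `truncated` flag set.
    """
    seq = coding_sequence.upper()
    if len(seq) % 3:
        raise ValueError("coding sequence length must be divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    weights = []
    for c in codons:
        if c in _STOP_CODONS:
            warnings.warn(f"stop codon {c} inside coding sequence excluded from tAI")
            weights.append(np.nan)
            continue
        w = codon_weights.get(c)
        if w is None or not 0 < w <= 1:
            raise ValueError(f"codon {c} missing from weight table or weight not in (0, 1]")
        weights.append(w)
    logw = np.log(np.asarray(weights, dtype=float))
    rows = []
    for prefix in prefix_lengths:
        label = "full" if prefix is None else f"first_{prefix}"
        take = len(codons) if prefix is None else min(prefix, len(codons))
        vals = logw[:take]
        vals = vals[np.isfinite(vals)]
        rows.append(
            {
                "prefix": label,
                "tai": float(np.exp(vals.mean())) if len(vals) else np.nan,
                "n_codons": int(len(vals)),
                "truncated": prefix is not None and prefix > len(codons),
            }
        )
    return pd.DataFrame(rows).set_index("prefix")


def overlap_degeneracy(sites: list[MotifSite]) -> dict:
    """Mean mismatch count of overlapping vs non-overlapping sites.

    Sites participating in at least one pairwise overlap form the
    "overlapping" category. Empty categories yield NaN means and the
    corresponding `*_defined` flag set to False.
    """
    involved: set[int] = set()
    for i, j in combinations(range(len(sites)), 2):
        if max(sites[i].start, sites[j].start) < min(sites[i].end, sites[j].end):
            involved.update((i, j))
    over = [s.n_mismatches for k, s in enumerate(sites) if k in involved]
    non = [s.n_mismatches for k, s in enumerate(sites) if k not in involved]
    mean_over = float(np.mean(over)) if over else np.nan
    mean_non = float(np.mean(non)) if non else np.nan
    return {
        "mean_mismatches_overlapping": mean_over,
        "mean_mismatches_non_overlapping": mean_non,
        "difference": mean_over - mean_non if over and non else np.nan,
        "overlapping_defined": bool(over),
        "non_overlapping_defined": bool(non),
    }
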