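"""K-mer catalogs, frequency ranking, and degenerate-class rank enrichment.

The central analysis: take the ±250 bp sequence windows around activated
peak centers, count every overlapping k-mer, rank the complete catalog of
4^k k-mers by frequency of appearance (rank 1 = most frequent), and ask
whether a degenerate sequence class — all-W, all-S, WWCGWW, and the like,
with W = A/T and S = C/G — sits unusually high (upward) or low (downward)
in that ranking, using Kolmogorov–Smirnov tests on the class's normalized
ranks.

Ties in counts receive midranks for all statistics; the lexicographic
tie-break is used only for the display order (top-N listings and "best
rank" queries). Reported p-values are floored at 1e-15.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

P_FLOOR = 1e-15

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "W": "AT", "S": "CG"}

_NUMBER_WORDS = {
    w: i
    for i, w in enumerate(
        "zero one two three four five six seven eight nine ten eleven twelve".split()
    )
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_kmer(kmer: str) -> int:
    idx = 0
    for base in kmer:
        code = _CODE[ord(base)]
        if code < 0:
            raise ValueError(f"non-ACGT letter in k-mer {kmer!r}")
        idx = idx * 4 + int(code)
    return idx


def decode_kmer(idx: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def _revcomp_permutation(k: int) -> np.ndarray:
    idx = np.arange(4**k)
    tmp = idx.copy()
    rc = np.zeros_like(idx)
    for _ in range(k):
        rc = rc * 4 + (3 - tmp % 4)
        tmp //= 4
    return rc


@dataclass
class KmerCatalog:
    """Complete count table over all 4^k k-mers, with optional ranks.

    ``counts[i]`` is the appearance count of the k-mer whose base-4
    encoding (A=0, C=1, G=2, T=3) is ``i``; numeric index order is exactly
    lexicographic k-mer order. ``ranks`` are midranks over descending
    counts; ``display_order`` lists encoded k-mers sorted by count
    descending with lexicographic tie-break.
    """

    k: int
    counts: np.ndarray
    n_windows: int
    strand_mode: str
    ranks: np.ndarray | None = None
    display_order: np.ndarray | None = None
    _display_position: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.counts) != 4**self.k:
            raise ValueError("counts must cover all 4^k k-mers")

    @property
    def size(self) -> int:
        return 4**self.k

    @property
    def is_ranked(self) -> bool:
        return self.ranks is not None

    def count(self, kmer: str) -> int:
        return int(self.counts[encode_kmer(kmer)])

    def rank(self, kmer: str) -> float:
        self._require_ranked()
        return float(self.ranks[encode_kmer(kmer)])

    def display_position(self, kmer: str) -> int:
        """1-based position of a k-mer in the display (top = 1) ordering."""
        self._require_ranked()
        return int(self._display_position[encode_kmer(kmer)]) + 1

    def top(self, n: int) -> list[str]:
        self._require_ranked()
        if not 1 <= n <= self.size:
            raise ValueError(f"n must lie in 1..{self.size}")
        return [decode_kmer(int(i), self.k) for i in self.display_order[:n]]

    def counts_by_kmer(self) -> dict[str, int]:
        return {
            decode_kmer(i, self.k): int(c) for i, c in enumerate(self.counts)
        }

    def _require_ranked(self) -> None:
        if not self.is_ranked:
            raise RuntimeError("catalog is not ranked; call rank_catalog first")


@dataclass(frozen=True)
class DegenerateClass:
    """A named set of concrete k-mers defined by W/S patterns or rules."""

    name: str
    member_set: frozenset[str]
    definition: str

    def __post_init__(self) -> None:
        if not self.member_set:
            raise ValueError(f"degenerate class {self.name!r} is empty")
        lengths = {len(m) for m in self.member_set}
        if len(lengths) != 1:
            raise ValueError("class members must share one k")

    @property
    def k(self) -> int:
        return len(next(iter(self.member_set)))


@dataclass(frozen=True)
class RankEnrichmentResult:
    """KS statistic, p, and direction for one class-rank comparison."""

    class_name: str
    n_members: int
    ks_statistic: float
    p_value: float
    direction: str  # upward | downward | none
    mode: str  # class_vs_catalog | class_vs_class | between_catalogs


@dataclass(frozen=True)
class TopSummary:
    """The top-N k-mers by display order with their mean GC% ± SE."""

    top_n: int
    kmers: tuple[str, ...]
    gc_mean: float
    gc_se: float


def extract_windows(
    genome: dict[str, str],
    centers: list[tuple[str, int]],
    half_width: int,
) -> list[str]:
    """±half_width windows (length 2·half_width + 1) around peak centers.

    Centers whose window would cross a contig boundary are dropped with a
    logged warning; input order is otherwise preserved.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    windows = []
    for contig, center in centers:
        if contig not in genome:
            raise ValueError(f"unknown contig {contig!r}")
        seq = genome[contig]
        lo, hi = center - half_width, center + half_width
        if lo < 0 or hi >= len(seq):
            logger.warning(
                "dropping center %s:%d: window [%d, %d] crosses contig boundary",
                contig,
                center,
                lo,
                hi,
            )
            continue
        windows.append(seq[lo : hi + 1])
    return windows


def count_kmers(windows: list[str], k: int, strand_mode: str = "both") -> KmerCatalog:
    """Count overlapping k-mers (step 1) over all windows.

    K-mers containing any non-ACGT letter are skipped. In ``both`` mode the
    reverse complement at every position is counted too, so
    counts[x] == counts[revcomp(x)] and the total doubles.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if strand_mode not in ("forward", "both"):
        raise ValueError("strand_mode must be 'forward' or 'both'")
    if windows and all(len(w) < k for w in windows):
        raise ValueError(f"k={k} is larger than every window")
    counts = np.zeros(4**k, dtype=np.int64)
    for window in windows:
        codes = _CODE[np.frombuffer(window.encode("ascii"), dtype=np.uint8)]
        n = len(codes) - k + 1
        if n <= 0:
            continue
        idx = np.zeros(n, dtype=np.int64)
        ok = np.ones(n, dtype=bool)
        for j in range(k):
            col = codes[j : j + n]
            idx = idx * 4 + col
            ok &= col >= 0
        counts += np.bincount(idx[ok], minlength=4**k)
    if strand_mode == "both":
        counts = counts + counts[_revcomp_permutation(k)]
    return KmerCatalog(
        k=k, counts=counts, n_windows=len(windows), strand_mode=strand_mode
    )


def rank_catalog(catalog: KmerCatalog) -> KmerCatalog:
    """Attach midranks (1 ≈ most frequent) and the display order.

    Midranks are averaged over count ties, so Σ ranks = N(N+1)/2 always;
    the display order breaks ties lexicographically (= numerically, by
    encoding).
    """
    ranks = stats.rankdata(-catalog.counts, method="average")
    order = np.lexsort((np.arange(catalog.size), -catalog.counts))
    position = np.empty(catalog.size, dtype=np.int64)
    position[order] = np.arange(catalog.size)
    return KmerCatalog(
        k=catalog.k,
        counts=catalog.counts,
        n_windows=catalog.n_windows,
        strand_mode=catalog.strand_mode,
        ranks=ranks,
        display_order=order,
        _display_position=position,
    )


def _parse_rule(text: str, *, k_hint: int | None = None) -> set[str] | None:
    """Parse a compositional rule like 'five S and one W'; None if not one."""
    m = re.fullmatch(
        r"\s*(\w+)\s+([WS])\s+and\s+(\w+)\s+([WS])\s*", text, flags=re.IGNORECASE
    )
    if m is None:
        return None
    n1, l1, n2, l2 = m.groups()
    counts = {}
    for n_text, letter in ((n1, l1.upper()), (n2, l2.upper())):
        n_text = n_text.lower()
        n = _NUMBER_WORDS.get(n_text)
        if n is None:
            if not n_text.isdigit():
                raise ValueError(f"cannot parse count {n_text!r} in rule {text!r}")
            n = int(n_text)
        counts[letter] = n
    if set(counts) != {"W", "S"}:
        raise ValueError(f"rule {text!r} must mention both W and S once")
    k = counts["W"] + counts["S"]
    if k_hint is not None and k != k_hint:
        raise ValueError(f"rule {text!r} implies k={k}, expected {k_hint}")
    members = set()
    for w_positions in itertools.combinations(range(k), counts["W"]):
        slots = ["AT" if i in w_positions else "CG" for i in range(k)]
        members.update("".join(p) for p in itertools.product(*slots))
    return members


def _expand_iupac(pattern: str) -> set[str]:
    slots = []
    for letter in pattern.upper():
        if letter not in _IUPAC:
            raise ValueError(
                f"unsupported letter {letter!r} in pattern {pattern!r}; "
                "supported: A C G T W S"
            )
        slots.append(_IUPAC[letter])
    return {"".join(p) for p in itertools.product(*slots)}


def expand_pattern(pattern: str, name: str | None = None) -> DegenerateClass:
    """Expand an IUPAC W/S pattern and/or compositional rule into a class.

    Alternatives are joined with "or": e.g. ``"SSSSSS or five S and one W"``
    expands to the 64 all-S 6-mers plus the 384 six-mers with exactly five
    S and one W (448 members).
    """
    members: set[str] = set()
    k_hint = None
    for part in re.split(r"\s+or\s+", pattern.strip(), flags=re.IGNORECASE):
        rule_members = _parse_rule(part, k_hint=k_hint)
        part_members = rule_members if rule_members is not None else _expand_iupac(part)
        if members and len(next(iter(part_members))) != k_hint:
            raise ValueError(f"alternatives in {pattern!r} have differing k")
        k_hint = len(next(iter(part_members)))
        members |= part_members
    return DegenerateClass(
        name=name or pattern, member_set=frozenset(members), definition=pattern
    )


def _normalized_ranks(catalog: KmerCatalog, cls: DegenerateClass) -> np.ndarray:
    if cls.k != catalog.k:
        raise ValueError(f"class k={cls.k} does not match catalog k={catalog.k}")
    idx = np.array(sorted(encode_kmer(m) for m in cls.member_set))
    return catalog.ranks[idx] / catalog.size


def _one_sample_ks_d(sample: np.ndarray) -> float:
    """sup_x |ECDF(x) − x| against the uniform CDF on (0, 1]."""
    x = np.sort(sample)
    n = len(x)
    grid = np.arange(1, n + 1) / n
    d_plus = float(np.max(grid - x))
    d_minus = float(np.max(x - (grid - 1 / n)))
    return max(d_plus, d_minus, 0.0)


def _direction(mean_focus: float, mean_reference: float) -> str:
    if mean_focus < mean_reference:
        return "upward"
    if mean_focus > mean_reference:
        return "downward"
    return "none"


def class_rank_ks(catalog: KmerCatalog, cls: DegenerateClass) -> RankEnrichmentResult:
    """One-sample KS test of the class's normalized ranks against uniform.

    Rank 1 is the most frequent k-mer, so a class whose normalized ranks
    pile up near zero is enriched "upward" (toward the top of the list).
    D is the sup deviation of the empirical CDF from the uniform CDF; the
    p-value comes from the Kolmogorov null distribution of D at the class
    size, floored at 1e-15. Direction compares the class's mean normalized
    rank with the full catalog's.
    """
    catalog._require_ranked()
    sample = _normalized_ranks(catalog, cls)
    d = _one_sample_ks_d(sample)
    p = float(stats.kstwo.sf(d, len(sample)))
    p = min(max(p, P_FLOOR), 1.0)
    direction = _direction(
        float(sample.mean()), float(catalog.ranks.mean() / catalog.size)
    )
    return RankEnrichmentResult(
        class_name=cls.name,
        n_members=len(sample),
        ks_statistic=d,
        p_value=p,
        direction=direction,
        mode="class_vs_catalog",
    )


def compare_class(
    catalog_a: KmerCatalog,
    other: "KmerCatalog | DegenerateClass",
    cls: DegenerateClass,
    mode: str | None = None,
) -> RankEnrichmentResult:
    """Two-sample KS comparison of rank distributions.

    ``between_catalogs`` (other is a catalog): the class's normalized ranks
    in catalog_a versus catalog_b; direction "upward" means the class rises
    toward the top going a → b. ``class_vs_class`` (other is a class): the
    ranks of ``cls`` versus ``other`` within catalog_a; "upward" means
    ``cls`` sits above ``other``.
    """
    catalog_a._require_ranked()
    if isinstance(other, KmerCatalog):
        mode = mode or "between_catalogs"
        if mode != "between_catalogs":
            raise ValueError("a second catalog implies mode='between_catalogs'")
        if other.k != catalog_a.k:
            raise ValueError("catalogs must share k")
        other._require_ranked()
        sample_a = _normalized_ranks(catalog_a, cls)
        sample_b = _normalized_ranks(other, cls)
        direction = _direction(float(sample_b.mean()), float(sample_a.mean()))
    elif isinstance(other, DegenerateClass):
        mode = mode or "class_vs_class"
        if mode != "class_vs_class":
            raise ValueError("a second class implies mode='class_vs_class'")
        sample_a = _normalized_ranks(catalog_a, cls)
        sample_b = _normalized_ranks(catalog_a, other)
        direction = _direction(float(sample_a.mean()), float(sample_b.mean()))
    else:
        raise TypeError("other must be a KmerCatalog or a DegenerateClass")
    if np.array_equal(np.sort(sample_a), np.sort(sample_b)):
        d, p = 0.0, 1.0
        direction = "none"
    else:
        result = stats.ks_2samp(sample_a, sample_b)
        d, p = float(result.statistic), float(result.pvalue)
    p = min(max(p, P_FLOOR), 1.0)
    return RankEnrichmentResult(
        class_name=cls.name,
        n_members=len(sample_a),
        ks_statistic=d,
        p_value=p,
        direction=direction,
        mode=mode,
    )


def gc_percent(kmer: str) -> float:
    return 100.0 * sum(b in "GC" for b in kmer) / len(kmer)


def top_summary(catalog: KmerCatalog, n: int) -> TopSummary:
    """The first n display-order k-mers with mean ± SE of their GC%."""
    kmers = catalog.top(n)
    gc = np.array([gc_percent(k) for k in kmers])
    se = float(gc.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return TopSummary(
        top_n=n, kmers=tuple(kmers), gc_mean=float(gc.mean()), gc_se=se
    )


def best_class_rank(catalog: KmerCatalog, cls: DegenerateClass) -> int:
    """Minimum (best) 1-based display position over the class's members."""
    catalog._require_ranked()
    if cls.k != catalog.k:
        raise ValueError("class k does not match catalog k")
    return min(catalog.display_position(m) for m in cls.member_set)
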