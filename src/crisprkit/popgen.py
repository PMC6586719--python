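"""Population-genetic statistics for gene-family coding alignments.

Implements the per-gene / per-domain diversity summaries used to survey a
gene family across a resequencing panel: Jukes–Cantor corrected nucleotide
diversity (pi), Watterson's theta, Tajima's D, Nei–Gojobori Ka/Ks with
pathway averaging, Kimura 2-parameter distances and a neighbor-joining
tree.

Conventions
-----------
* Gaps (``-``) and ``N`` are missing data, never a fifth state.
* pi and K2P use pairwise deletion; the segregating-site count and
  Tajima's D use complete deletion (columns with any gap/N dropped).
* Jukes–Cantor correction is applied to reported pi; Tajima's D is
  computed from the *uncorrected* mean pairwise difference count.
* Neighbor-joining breaks Q-matrix ties by joining the lexicographically
  smallest label pair, so output is deterministic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

VALID_CHARS = set("ACGTN-")
MISSING = set("N-")
PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}

STANDARD_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

BASES = "ACGT"


class SaturationError(ValueError):
    """Observed divergence exceeds what the distance correction can invert."""


class InsufficientSamplesError(ValueError):
    """Fewer sequences than the statistic requires."""


@dataclass
class CodingAlignment:
    """A gapped, length-aligned set of nucleotide sequences.

    Parameters
    ----------
    sample_ids : labels, one per sequence.
    sequences : equal-length strings over ``ACGTN-`` (case-insensitive).
    frame_offset : bases to skip before the first complete codon.
    domains : optional ``(name, start, end)`` regions, 1-based inclusive
        in alignment coordinates.
    """

    sample_ids: list[str]
    sequences: list[str]
    frame_offset: int = 0
    domains: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.sequences):
            raise ValueError("sample_ids and sequences differ in length")
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        for s in self.sequences:
            bad = set(s) - VALID_CHARS
            if bad:
                raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
        for name, start, end in self.domains:
            if not (1 <= start <= end <= self.length):
                raise ValueError(
                    f"domain {name!r} interval ({start},{end}) outside [1,{self.length}]"
                )

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def domain_names(self) -> list[str]:
        return [d[0] for d in self.domains]

    def slice_region(self, name: str) -> "CodingAlignment":
        """Extract one declared domain as a new alignment (domains dropped)."""
        for dname, start, end in self.domains:
            if dname == name:
                return CodingAlignment(
                    sample_ids=list(self.sample_ids),
                    sequences=[s[start - 1 : end] for s in self.sequences],
                    frame_offset=0,
                )
        raise KeyError(f"no domain named {name!r}")


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if (self.values < 0).any():
            raise ValueError("distance matrix has negative entries")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("distance matrix diagonal is not zero")


@dataclass
class PopGenSummary:
    """Per-region diversity summary row."""

    region_name: str
    n: int
    S: int
    pi_raw: float
    pi_jc: float
    theta_w: float
    ka: float
    ks: float
    ka_ks: float
    tajima_d: float

    FIELDS = (
        "region_name n S pi_raw pi_jc theta_w ka ks ka_ks tajima_d".split()
    )


# ---------------------------------------------------------------------------
# distances

def jc_corrected_distance(p: float) -> float:
    """Jukes–Cantor corrected distance d = -(3/4) ln(1 - 4p/3).

    Raises
    ------
    ValueError if p < 0, SaturationError if p >= 3/4.
    """
    if p < 0:
        raise ValueError(f"difference proportion must be >= 0, got {p}")
    if p >= 0.75:
        raise SaturationError(f"p = {p} >= 3/4: JC correction saturates")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _pairwise_p(s1: str, s2: str) -> tuple[int, int]:
    """(differences, comparable sites) with pairwise gap/N exclusion."""
    diffs = valid = 0
    for a, b in zip(s1, s2):
        if a in MISSING or b in MISSING:
            continue
        valid += 1
        if a != b:
            diffs += 1
    return diffs, valid


def k2p_distance(seq1: str, seq2: str) -> float:
    """Kimura 2-parameter distance K = -ln(1-2P-Q)/2 - ln(1-2Q)/4."""
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2):
        raise ValueError("sequences must have equal length")
    transitions = transversions = valid = 0
    for a, b in zip(seq1, seq2):
        if a in MISSING or b in MISSING:
            continue
        valid += 1
        if a == b:
            continue
        if (a in PURINES) == (b in PURINES):
            transitions += 1
        else:
            transversions += 1
    if valid == 0:
        return math.nan
    P, Q = transitions / valid, transversions / valid
    arg1, arg2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if arg1 <= 0 or arg2 <= 0:
        raise SaturationError(
            f"K2P saturated: P={P:.4f}, Q={Q:.4f} give a non-positive log argument"
        )
    return -0.5 * math.log(arg1) - 0.25 * math.log(arg2)


def k2p_matrix(aln: CodingAlignment) -> DistanceMatrix:
    n = aln.n
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = k2p_distance(aln.sequences[i], aln.sequences[j])
        m[i, j] = m[j, i] = d
    return DistanceMatrix(labels=list(aln.sample_ids), values=m)


# ---------------------------------------------------------------------------
# diversity

def nucleotide_diversity(
    aln: CodingAlignment, region: str | None = None, corrected: bool = False
) -> float:
    """Mean pairwise per-site difference proportion (pi).

    Sites with a gap or N in either member of a pair are excluded for that
    pair only. With ``corrected``, each pairwise proportion is JC-corrected
    before averaging. Returns NaN when every site is masked in every pair.
    """
    if region is not None:
        aln = aln.slice_region(region)
    if aln.n < 2:
        raise InsufficientSamplesError("nucleotide diversity needs n >= 2")
    vals = []
    for s1, s2 in itertools.combinations(aln.sequences, 2):
        diffs, valid = _pairwise_p(s1, s2)
        if valid == 0:
            continue
        p = diffs / valid
        vals.append(jc_corrected_distance(p) if corrected else p)
    if not vals:
        return math.nan
    return float(np.mean(vals))


def _complete_deletion_columns(aln: CodingAlignment) -> list[tuple[str, ...]]:
    cols = []
    for col in zip(*aln.sequences):
        if any(c in MISSING for c in col):
            continue
        cols.append(col)
    return cols


def segregating_sites(aln: CodingAlignment) -> int:
    """Number of polymorphic columns under complete deletion."""
    return sum(1 for col in _complete_deletion_columns(aln) if len(set(col)) > 1)


def mean_pairwise_differences(aln: CodingAlignment) -> float:
    """Mean pairwise difference *count* k-hat under complete deletion."""
    cols = _complete_deletion_columns(aln)
    n = aln.n
    total = 0
    for col in cols:
        for a, b in itertools.combinations(col, 2):
            if a != b:
                total += 1
    npairs = n * (n - 1) // 2
    return total / npairs if npairs else math.nan


def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 normalising constants of Tajima's D for sample size n."""
    if n < 2:
        raise InsufficientSamplesError("Tajima constants need n >= 2")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def tajimas_d_from_stats(n: int, S: int, khat: float) -> float:
    """Tajima's D from sample size, segregating sites and k-hat.

    Returns NaN when S = 0 (the statistic is undefined, not zero).
    """
    if S == 0:
        return math.nan
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return (khat - S / c["a1"]) / math.sqrt(var)


def tajimas_d(aln: CodingAlignment) -> float:
    """Tajima's D of an alignment (complete deletion, uncorrected k-hat)."""
    if aln.n < 4:
        raise InsufficientSamplesError("Tajima's D needs n >= 4")
    S = segregating_sites(aln)
    khat = mean_pairwise_differences(aln)
    return tajimas_d_from_stats(aln.n, S, khat)


def watterson_theta(aln: CodingAlignment) -> float:
    """Watterson's estimator S / a1 for the whole region."""
    return segregating_sites(aln) / tajima_constants(aln.n)["a1"]


# ---------------------------------------------------------------------------
# Nei–Gojobori

def _syn_fraction(codon: str, pos: int) -> float:
    """Fraction of the three possible changes at `pos` that are synonymous.

    Changes creating a stop codon count as nonsynonymous (N + S = 3 per
    codon position set).
    """
    aa = STANDARD_CODE[codon]
    syn = 0
    for b in BASES:
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if STANDARD_CODE[alt] == aa:
            syn += 1
    return syn / 3.0


def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) potential sites of one codon; sums to 3."""
    s = sum(_syn_fraction(codon, pos) for pos in range(3))
    return s, 3.0 - s


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) observed differences between two codons.

    Codons differing at k positions are scored over all k! substitution
    orderings; orderings passing through a stop codon are discarded. If
    every ordering is blocked by a stop, all orderings are used instead so
    the difference count is preserved.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    scored = []
    blocked = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if STANDARD_CODE[nxt] == "*" and nxt != c2:
                hit_stop = True
            if STANDARD_CODE[cur] == STANDARD_CODE[nxt] and STANDARD_CODE[nxt] != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if hit_stop else scored).append((sd, nd))
    use = scored if scored else blocked
    sd = sum(x[0] for x in use) / len(use)
    nd = sum(x[1] for x in use) / len(use)
    return sd, nd


def nei_gojobori(cds1: str, cds2: str) -> tuple[float, float, float]:
    """Nei–Gojobori (Ka, Ks, Ka/Ks) between two in-frame CDSs.

    Potential sites are averaged between the two sequences; observed
    differences are pathway-averaged; pN and pS are JC-corrected. Codons
    containing a gap, N or stop in either sequence are skipped. Ka/Ks is
    NaN when Ks = 0.

    Raises
    ------
    ValueError on length mismatch or length not divisible by 3;
    SaturationError when pS or pN >= 3/4.
    """
    cds1, cds2 = cds1.upper(), cds2.upper()
    if len(cds1) != len(cds2):
        raise ValueError("CDS lengths differ")
    if len(cds1) % 3:
        raise ValueError("CDS length not divisible by 3")
    S_sites = N_sites = 0.0
    Sd = Nd = 0.0
    for i in range(0, len(cds1), 3):
        c1, c2 = cds1[i : i + 3], cds2[i : i + 3]
        if not (set(c1) <= set(BASES) and set(c2) <= set(BASES)):
            continue  # codon-level pairwise deletion of gap/N codons
        if STANDARD_CODE[c1] == "*" or STANDARD_CODE[c2] == "*":
            if i + 3 < len(cds1):
                raise ValueError("internal stop codon")
            continue
        s1, n1 = codon_sites(c1)
        s2, n2 = codon_sites(c2)
        S_sites += (s1 + s2) / 2.0
        N_sites += (n1 + n2) / 2.0
        sd, nd = _pathway_counts(c1, c2)
        Sd += sd
        Nd += nd
    pS = Sd / S_sites if S_sites else 0.0
    pN = Nd / N_sites if N_sites else 0.0
    ks = jc_corrected_distance(pS)
    ka = jc_corrected_distance(pN)
    ka_ks = ka / ks if ks > 0 else math.nan
    return ka, ks, ka_ks


def mean_pairwise_ka_ks(sequences: Sequence[str]) -> tuple[float, float, float]:
    """Mean pairwise Ka and Ks over all sequence pairs; ratio of the means."""
    kas, kss = [], []
    for s1, s2 in itertools.combinations(sequences, 2):
        ka, ks, _ = nei_gojobori(s1, s2)
        kas.append(ka)
        kss.append(ks)
    if not kas:
        return math.nan, math.nan, math.nan
    ka, ks = float(np.mean(kas)), float(np.mean(kss))
    return ka, ks, (ka / ks if ks > 0 else math.nan)


# ---------------------------------------------------------------------------
# neighbor joining

def neighbor_joining(dm: DistanceMatrix) -> str:
    """Saitou–Nei neighbor joining; returns an unrooted tree in Newick form.

    Ties in the Q matrix are broken by joining the lexicographically
    smallest (label_i, label_j) pair. Negative branch lengths are clamped
    to zero with the deficit shifted onto the sister branch.
    """
    if len(dm.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    labels = list(dm.labels)
    # each active node: (sort_key, newick_subtree)
    nodes: dict[int, tuple[str, str]] = {
        i: (lab, lab) for i, lab in enumerate(labels)
    }
    d = {
        (i, j): dm.values[i, j]
        for i in range(len(labels))
        for j in range(len(labels))
        if i != j
    }
    next_id = len(labels)
    active = set(nodes)

    def dist(i: int, j: int) -> float:
        return 0.0 if i == j else d[(i, j)]

    while len(active) > 2:
        r = len(active)
        totals = {i: sum(dist(i, k) for k in active) for i in active}
        best = None
        for i, j in itertools.combinations(sorted(active), 2):
            q = (r - 2) * dist(i, j) - totals[i] - totals[j]
            key_pair = tuple(sorted((nodes[i][0], nodes[j][0])))
            cand = (q, key_pair, i, j)
            if best is None or cand[:2] < best[:2]:
                best = cand
        _, _, i, j = best
        dij = dist(i, j)
        li = 0.5 * dij + (totals[i] - totals[j]) / (2.0 * (r - 2))
        lj = dij - li
        # clamp negatives, shifting the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = next_id
        next_id += 1
        key = min(nodes[i][0], nodes[j][0])
        nwk = f"({nodes[i][1]}:{li:.6f},{nodes[j][1]}:{lj:.6f})"
        nodes[new] = (key, nwk)
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (dist(i, k) + dist(j, k) - dij)
            d[(new, k)] = d[(k, new)] = max(dk, 0.0)
        active -= {i, j}
        active.add(new)

    i, j = sorted(active)
    dij = dist(i, j)
    return f"({nodes[i][1]}:{dij:.6f},{nodes[j][1]}:0.000000);"


# ---------------------------------------------------------------------------
# per-region scan

def _region_summary(aln: CodingAlignment, name: str) -> PopGenSummary:
    n = aln.n
    try:
        pi_raw = nucleotide_diversity(aln)
        pi_jc = nucleotide_diversity(aln, corrected=True)
    except (InsufficientSamplesError, SaturationError):
        pi_raw = pi_jc = math.nan
    S = segregating_sites(aln)
    theta = S / tajima_constants(n)["a1"] if n >= 2 else math.nan
    try:
        D = tajimas_d(aln) if n >= 4 else math.nan
    except InsufficientSamplesError:
        D = math.nan
    if aln.length % 3 == 0 and aln.length >= 3:
        try:
            ka, ks, ka_ks = mean_pairwise_ka_ks(aln.sequences)
        except (ValueError, SaturationError):
            ka = ks = ka_ks = math.nan
    else:
        ka = ks = ka_ks = math.nan
    return PopGenSummary(
        region_name=name, n=n, S=S, pi_raw=pi_raw, pi_jc=pi_jc,
        theta_w=theta, ka=ka, ks=ks, ka_ks=ka_ks, tajima_d=D,
    )


def domain_scan(aln: CodingAlignment) -> list[PopGenSummary]:
    """Whole-CDS summary followed by one summary per declared domain.

    Domain slices are snapped outward to codon boundaries (relative to the
    alignment frame) so Ka/Ks stays well defined.
    """
    rows = [_region_summary(aln, "CDS")]
    for name, start, end in aln.domains:
        s0 = start - 1 - (start - 1 - aln.frame_offset) % 3
        s0 = max(s0, aln.frame_offset)
        e0 = end + (-(end - aln.frame_offset) % 3)
        e0 = min(e0, aln.length)
        sub = CodingAlignment(
            sample_ids=list(aln.sample_ids),
            sequences=[s[s0:e0] for s in aln.sequences],
        )
        rows.append(_region_summary(sub, name))
    return rows
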