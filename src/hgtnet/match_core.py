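"""Maximal exact matches (MEMs) between bacterial genomes.

Long identical segments shared by genomes from different genera are the raw
signal of recent horizontal gene transfer: point mutations destroy perfect
identity quickly, so a multi-kilobase exact match implies a very recent common
origin of that segment.  This module finds every maximal exact match between
two genomes, intersects pairwise matches into regions identical across n > 2
genera, and counts the genome comparisons used to normalize match-length
distributions.

Conventions
-----------
* Coordinates are 0-based, half-open throughout (the TSV writer can emit
  1-based starts for interoperability).
* Only the forward strand is searched by default.
* Characters outside {A, C, G, T} act as universal mismatches: they terminate
  matches and never match anything, including themselves.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InputError",
    "GenomeRecord",
    "MatchRecord",
    "MultiMatch",
    "ComparisonCount",
    "find_maximal_exact_matches",
    "find_maximal_exact_matches_bruteforce",
    "intersect_to_multimatch",
    "find_multimatches",
    "count_comparisons",
    "read_genomes",
    "write_matches_tsv",
    "read_matches_tsv",
    "write_multimatches_tsv",
]


class InputError(ValueError):
    """Raised when input data violate a documented precondition."""


_ACGT = frozenset("ACGT")
# Distinct per-role sentinels so that a masked symbol in one genome can never
# equal a masked symbol in the other genome (N must not match N).
_MASK_A = "\x01"
_MASK_B = "\x02"
_NON_ACGT = re.compile(r"[^ACGT]")


@dataclass(frozen=True)
class GenomeRecord:
    """A single genome (or replicon) with its genus label.

    ``sequence`` is uppercased on construction; symbols outside A/C/G/T are
    kept verbatim and treated as universal mismatches by the match finder.
    """

    genome_id: str
    taxon: str
    sequence: str
    replicon_tag: str | None = None

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise InputError("genome_id must be nonempty")
        if not self.taxon:
            raise InputError("taxon must be nonempty")
        if not self.sequence:
            raise InputError(f"genome {self.genome_id!r}: empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class MatchRecord:
    """A maximal exact match between two genomes (0-based, half-open)."""

    genome_a: str
    genome_b: str
    start_a: int
    start_b: int
    length: int


@dataclass(frozen=True)
class MultiMatch:
    """A region identical across one genome from each of n genera.

    ``ref_interval`` is the half-open interval on the first (reference)
    genome; the same sequence occurs verbatim in every listed genome.
    """

    genus_set: tuple[str, ...]
    genomes: tuple[str, ...]
    ref_start: int
    ref_end: int

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass(frozen=True)
class ComparisonCount:
    """Per-genus genome counts k_1..k_n and their product.

    The total is the number of genome comparisons performed for the genus
    set; the match-length distribution is divided by it.
    """

    genus_set: tuple[str, ...]
    counts: tuple[int, ...]
    total: int


# ---------------------------------------------------------------------------
# MEM finding
# ---------------------------------------------------------------------------


def _mask(seq: str, sentinel: str) -> str:
    return _NON_ACGT.sub(sentinel, seq)


def _common_prefix_len(a: str, i: int, b: str, j: int) -> int:
    """Length of the longest common prefix of a[i:] and b[j:] (chunked)."""
    n = 0
    step = 64
    la, lb = len(a), len(b)
    while True:
        ca = a[i + n : i + n + step]
        cb = b[j + n : j + n + step]
        if ca == cb:
            if not ca:
                return n
            n += len(ca)
            if i + n >= la or j + n >= lb:
                return n
            step *= 2
        else:
            m = min(len(ca), len(cb))
            for t in range(m):
                if ca[t] != cb[t]:
                    return n + t
            return n + m


def _common_suffix_len(a: str, i: int, b: str, j: int) -> int:
    """Length of the longest common suffix of a[:i] and b[:j] (chunked)."""
    n = 0
    step = 64
    while True:
        lo_a = max(i - n - step, 0)
        lo_b = max(j - n - step, 0)
        ca = a[lo_a : i - n]
        cb = b[lo_b : j - n]
        if ca == cb:
            if not ca:
                return n
            n += len(ca)
            if i - n == 0 or j - n == 0:
                return n
            step *= 2
        else:
            m = min(len(ca), len(cb))
            for t in range(1, m + 1):
                if ca[-t] != cb[-t]:
                    return n + t - 1
            return n + m


def _seq_of(g) -> str:
    return g.sequence if isinstance(g, GenomeRecord) else str(g)


# Base-coding for the rolling seed hash: A/C/G/T -> 1..4 and role-specific
# codes for masked symbols so a masked position never equals anything.
_CODE_A = np.zeros(256, dtype=np.uint64)
_CODE_B = np.zeros(256, dtype=np.uint64)
for _i, _c in enumerate(b"ACGT"):
    _CODE_A[_c] = _i + 1
    _CODE_B[_c] = _i + 1
_CODE_A[ord(_MASK_A)] = 5
_CODE_B[ord(_MASK_B)] = 6

_HASH_BASE = np.uint64(0x9E3779B97F4A7C15)  # odd => invertible mod 2^64
_HASH_BASE_INV = np.uint64(pow(int(_HASH_BASE), -1, 2**64))


def _kmer_hashes(seq: str, k: int, code: np.ndarray) -> np.ndarray:
    """Polynomial rolling hash of every k-mer, mod 2^64 (wraparound).

    hash_j = sum_t code[seq[j+t]] * B^(k-1-t); computed from prefix sums of
    code * B^-t so the whole array is one vectorized pass.
    """
    c = code[np.frombuffer(seq.encode("latin-1"), np.uint8)]
    n = c.size - k + 1
    inv_pow = np.empty(c.size, dtype=np.uint64)
    inv_pow[0] = 1
    np.cumprod(np.full(c.size - 1, _HASH_BASE_INV, dtype=np.uint64), out=inv_pow[1:])
    prefix = np.zeros(c.size + 1, dtype=np.uint64)
    np.cumsum(c * inv_pow, out=prefix[1:])
    fwd_pow = np.empty(n, dtype=np.uint64)
    fwd_pow[0] = _HASH_BASE ** np.uint64(k - 1)
    np.cumprod(np.full(n - 1, _HASH_BASE, dtype=np.uint64), out=fwd_pow[1:])
    fwd_pow[1:] *= fwd_pow[0]
    return (prefix[k : k + n] - prefix[:n]) * fwd_pow


def find_maximal_exact_matches(
    a: GenomeRecord | str,
    b: GenomeRecord | str,
    min_len: int = 1000,
) -> list[MatchRecord]:
    """Find all maximal exact matches of length >= ``min_len``.

    A match is maximal when extending it by one position on either side
    either leaves a genome boundary or produces a mismatch.  Every occurrence
    pair of a repeated maximal substring is reported once.

    The finder seeds on exact k-mers with k = min(min_len, 32): any maximal
    match of length >= min_len contains its own first k-mer, so seeding is
    lossless; a per-diagonal coverage map guarantees each occurrence pair is
    extended exactly once.  Runs in O(L) expected time on random sequences.
    """
    if min_len < 2:
        raise InputError("min_len must be >= 2")
    sa, sb = _seq_of(a), _seq_of(b)
    if not sa or not sb:
        raise InputError("sequences must be non-empty")
    id_a = a.genome_id if isinstance(a, GenomeRecord) else "a"
    id_b = b.genome_id if isinstance(b, GenomeRecord) else "b"
    sa = _mask(sa.upper(), _MASK_A)
    sb = _mask(sb.upper(), _MASK_B)

    k = min(min_len, 32)
    if len(sa) < k or len(sb) < k:
        return []

    ha = _kmer_hashes(sa, k, _CODE_A)
    hb = _kmer_hashes(sb, k, _CODE_B)
    order_a = np.argsort(ha)
    ha_sorted = ha[order_a]
    # positions in b whose seed hash occurs in a (vectorized membership)
    lo = np.searchsorted(ha_sorted, hb, side="left")
    hi = np.searchsorted(ha_sorted, hb, side="right")
    candidates = np.flatnonzero(hi > lo)

    out: list[MatchRecord] = []
    covered: dict[int, int] = {}  # diagonal (i - j) -> exclusive end in b coords
    for j in map(int, candidates):
        seed_b = sb[j : j + k]
        for i in map(int, order_a[lo[j] : hi[j]]):
            d = i - j
            if covered.get(d, 0) > j:
                continue
            if sa[i : i + k] != seed_b:  # 64-bit hash collision guard
                continue
            left = _common_suffix_len(sa, i, sb, j)
            right = _common_prefix_len(sa, i + k, sb, j + k)
            length = k + left + right
            covered[d] = j + k + right
            if length >= min_len:
                out.append(MatchRecord(id_a, id_b, i - left, j - left, length))
    out.sort(key=lambda m: (m.start_a, m.start_b))
    return out


def find_maximal_exact_matches_bruteforce(
    a: GenomeRecord | str,
    b: GenomeRecord | str,
    min_len: int = 1000,
) -> list[MatchRecord]:
    """O(L^2) reference implementation: equality matrix, runs per diagonal.

    Independent of the seed-and-extend path; intended for validation on
    sequences up to a few kilobases.
    """
    if min_len < 2:
        raise InputError("min_len must be >= 2")
    sa, sb = _seq_of(a), _seq_of(b)
    if not sa or not sb:
        raise InputError("sequences must be non-empty")
    id_a = a.genome_id if isinstance(a, GenomeRecord) else "a"
    id_b = b.genome_id if isinstance(b, GenomeRecord) else "b"
    xa = np.frombuffer(_mask(sa.upper(), _MASK_A).encode("latin-1"), np.uint8)
    xb = np.frombuffer(_mask(sb.upper(), _MASK_B).encode("latin-1"), np.uint8)

    out: list[MatchRecord] = []
    la, lb = len(xa), len(xb)
    for d in range(-(lb - 1), la):
        i0 = max(d, 0)
        j0 = max(-d, 0)
        n = min(la - i0, lb - j0)
        if n < min_len:
            continue
        eq = xa[i0 : i0 + n] == xb[j0 : j0 + n]
        # maximal runs of True
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for s, e in zip(starts, ends):
            if e - s >= min_len:
                out.append(MatchRecord(id_a, id_b, i0 + int(s), j0 + int(s), int(e - s)))
    out.sort(key=lambda m: (m.start_a, m.start_b))
    return out


# ---------------------------------------------------------------------------
# Intersection to multi-genus matches
# ---------------------------------------------------------------------------


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not iv:
        return []
    iv = sorted(iv)
    merged = [iv[0]]
    for s, e in iv[1:]:
        ls, le = merged[-1]
        if s <= le:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def _intersect_two(u: list[tuple[int, int]], v: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    while i < len(u) and j < len(v):
        s = max(u[i][0], v[j][0])
        e = min(u[i][1], v[j][1])
        if s < e:
            out.append((s, e))
        if u[i][1] < v[j][1]:
            i += 1
        else:
            j += 1
    return out


def intersect_to_multimatch(
    pairwise: Mapping[str, Sequence[MatchRecord]],
    min_len: int,
    ref_genus: str,
) -> list[MultiMatch]:
    """Intersect pairwise matches anchored on one reference genome.

    ``pairwise`` maps each partner genus to the matches between the shared
    reference genome (``genome_a`` of every record) and one genome of that
    genus.  Because exact identity is transitive, projecting each partner's
    matches onto the reference and taking the position-wise intersection
    yields exactly the regions identical across all genera.  Maximal
    intersection intervals of length >= ``min_len`` are returned.
    """
    if not pairwise:
        raise InputError("need at least one partner genus")
    ref_ids = {m.genome_a for ms in pairwise.values() for m in ms}
    if len(ref_ids) > 1:
        raise InputError(f"pairwise lists anchored on different references: {sorted(ref_ids)}")
    ref_id = ref_ids.pop() if ref_ids else ""

    partner_ids = []
    projected: list[list[tuple[int, int]]] = []
    for genus, ms in pairwise.items():
        ids = {m.genome_b for m in ms}
        if len(ids) > 1:
            raise InputError(f"genus {genus!r}: more than one partner genome ({sorted(ids)})")
        partner_ids.append(ids.pop() if ids else f"<{genus}>")
        projected.append(_merge_intervals([(m.start_a, m.start_a + m.length) for m in ms]))

    common = projected[0]
    for iv in projected[1:]:
        common = _intersect_two(common, iv)
        if not common:
            break

    genus_set = (ref_genus, *pairwise.keys())
    genomes = (ref_id, *partner_ids)
    return [
        MultiMatch(genus_set, genomes, s, e)
        for s, e in common
        if e - s >= min_len
    ]


def find_multimatches(
    collection: Iterable[GenomeRecord],
    genus_set: Sequence[str],
    min_len: int = 1000,
) -> list[MultiMatch]:
    """All multi-genus matches for a genus set over a genome collection.

    Runs one extraction per combination of one genome per genus, anchored on
    each genome of the first genus in turn; duplicate intervals arising from
    different anchors are kept (normalization by k_1...k_n accounts for the
    number of combinations).  For a pair, pairwise MEMs are converted
    directly.
    """
    genomes = list(collection)
    by_genus: dict[str, list[GenomeRecord]] = {}
    for g in genomes:
        by_genus.setdefault(g.taxon, []).append(g)
    for genus in genus_set:
        if genus not in by_genus:
            raise InputError(f"genus {genus!r} not present in collection")
    if len(genus_set) < 2:
        raise InputError("genus_set must contain at least two genera")

    out: list[MultiMatch] = []
    ref_genus, *partners = genus_set
    pair_cache: dict[tuple[str, str], list[MatchRecord]] = {}

    def pair_matches(ref: GenomeRecord, other: GenomeRecord) -> list[MatchRecord]:
        key = (ref.genome_id, other.genome_id)
        if key not in pair_cache:
            pair_cache[key] = find_maximal_exact_matches(ref, other, min_len)
        return pair_cache[key]

    for ref in by_genus[ref_genus]:
        if not partners:
            continue
        for combo in itertools.product(*(by_genus[g] for g in partners)):
            pairwise = {
                g.taxon: pair_matches(ref, g)
                for g in combo
            }
            if len(partners) == 1:
                g = combo[0]
                out.extend(
                    MultiMatch((ref_genus, g.taxon), (ref.genome_id, g.genome_id),
                               m.start_a, m.start_a + m.length)
                    for m in pairwise[g.taxon]
                )
            else:
                out.extend(intersect_to_multimatch(pairwise, min_len, ref_genus))
    return out


def count_comparisons(
    collection: Iterable[GenomeRecord],
    genus_set: Sequence[str],
) -> ComparisonCount:
    """Number of genome comparisons k_1 * k_2 * ... * k_n for a genus set."""
    counts: dict[str, int] = {}
    for g in collection:
        counts[g.taxon] = counts.get(g.taxon, 0) + 1
    ks = []
    for genus in genus_set:
        if genus not in counts:
            raise InputError(f"genus {genus!r} not present in collection")
        ks.append(counts[genus])
    total = 1
    for k in ks:
        total *= k
    return ComparisonCount(tuple(genus_set), tuple(ks), total)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def read_genomes(fasta_path: str | Path, manifest_path: str | Path) -> list[GenomeRecord]:
    """Read genomes from FASTA plus a genome_id -> genus TSV manifest.

    The manifest has columns ``genome_id``, ``taxon`` and optionally
    ``replicon_tag``; FASTA record ids are matched against ``genome_id``.
    """
    from Bio import SeqIO

    manifest = pd.read_csv(manifest_path, sep="\t", dtype=str)
    required = {"genome_id", "taxon"}
    if not required.issubset(manifest.columns):
        raise InputError(f"manifest must have columns {sorted(required)}")
    meta = manifest.set_index("genome_id")

    out = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in meta.index:
            raise InputError(f"genome {rec.id!r} missing from manifest")
        row = meta.loc[rec.id]
        tag = row.get("replicon_tag")
        out.append(
            GenomeRecord(
                genome_id=rec.id,
                taxon=str(row["taxon"]),
                sequence=str(rec.seq),
                replicon_tag=None if tag is None or pd.isna(tag) else str(tag),
            )
        )
    ids = [g.genome_id for g in out]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate genome ids in FASTA")
    return out


def write_matches_tsv(matches: Sequence[MatchRecord], path: str | Path, one_based: bool = False) -> None:
    off = 1 if one_based else 0
    df = pd.DataFrame(
        {
            "genome_a": [m.genome_a for m in matches],
            "genome_b": [m.genome_b for m in matches],
            "start_a": [m.start_a + off for m in matches],
            "start_b": [m.start_b + off for m in matches],
            "length": [m.length for m in matches],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_matches_tsv(path: str | Path) -> list[MatchRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        MatchRecord(str(r.genome_a), str(r.genome_b), int(r.start_a), int(r.start_b), int(r.length))
        for r in df.itertuples()
    ]


def write_multimatches_tsv(mms: Sequence[MultiMatch], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "genus_set": [",".join(m.genus_set) for m in mms],
            "genomes": [",".join(m.genomes) for m in mms],
            "ref_start": [m.ref_start for m in mms],
            "ref_end": [m.ref_end for m in mms],
            "length": [m.length for m in mms],
        }
    )
    df.to_csv(path, sep="\t", index=False)
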