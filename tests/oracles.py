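"""Independent brute-force implementations used as test oracles.

These deliberately share no code with the package: plain dict/str/loop
implementations, with codon translation delegated to Biopython.
"""

from __future__ import annotations

import itertools
import math

from Bio.Seq import Seq

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(word: str) -> str:
    return "".join(COMP[b] for b in reversed(word))


def canon(word: str) -> str:
    r = rc(word)
    return word if word <= r else r


def naive_kmer_count(seqs, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seq in seqs:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if any(b not in "ACGT" for b in w):
                continue
            c = canon(w)
            counts[c] = counts.get(c, 0) + 1
    return counts


def naive_kmer_set(seqs, k: int) -> set[str]:
    return set(naive_kmer_count(seqs, k))


def naive_substring_hits(kmer_words: set[str], contig: str, k: int) -> list[int]:
    """Start positions where contig matches any query word on either strand."""
    both = set(kmer_words) | {rc(w) for w in kmer_words}
    hits = []
    for i in range(len(contig) - k + 1):
        if contig[i : i + k] in both:
            hits.append(i)
    return hits


def naive_window_scan(length: int, snps: set[int], mask: set[int],
                      window: int, step: int, k: int) -> list[int]:
    """Per-window conserved k-mer site counts, single scaffold."""
    bad = snps | mask
    out = []
    start = 0
    while start + window <= length:
        n = 0
        for p in range(start, start + window - k + 1):
            if all(q not in bad for q in range(p, p + k)):
                n += 1
        out.append(n)
        start += step
    return out


from functools import lru_cache


@lru_cache(maxsize=None)
def translate(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_codon_sites(seq: str) -> tuple[float, float]:
    """(S, N): stop-target changes excluded, denominator 3 per position."""
    S = N = 0.0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        aa = translate(codon)
        for pos in range(3):
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1 :]
                alt_aa = translate(alt)
                if alt_aa == "*":
                    continue
                if alt_aa == aa:
                    S += 1 / 3
                else:
                    N += 1 / 3
    return S, N


def oracle_pathway_diffs(a: str, b: str) -> tuple[float, float]:
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff):
        cur, sd, nd, ok = a, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if translate(nxt) == "*":
                ok = False
            if translate(nxt) == translate(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((ok, sd, nd))
    valid = [(s, n) for ok, s, n in results if ok]
    if not valid:
        valid = [(s, n) for _, s, n in results]
    return (sum(s for s, _ in valid) / len(valid),
            sum(n for _, n in valid) / len(valid))


def oracle_ng86(seq_a: str, seq_b: str) -> tuple[float, float]:
    """(dS, dN); nan on saturation."""
    sa, na = oracle_codon_sites(seq_a)
    sb, nb = oracle_codon_sites(seq_b)
    s_mean, n_mean = (sa + sb) / 2, (na + nb) / 2
    sd = nd = 0.0
    for i in range(0, len(seq_a), 3):
        s, n = oracle_pathway_diffs(seq_a[i : i + 3], seq_b[i : i + 3])
        sd += s
        nd += n
    ps, pn = sd / s_mean, nd / n_mean

    def jc(p):
        return float("nan") if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    return jc(ps), jc(pn)


def all_sense_codons() -> list[str]:
    return [
        "".join(c) for c in itertools.product("ACGT", repeat=3)
        if translate("".join(c)) != "*"
    ]
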