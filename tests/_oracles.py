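"""Independent brute-force reference implementations used only by tests.

Each oracle is written directly from the defining formula or by explicit
enumeration, sharing no code with the package's vectorized implementations.
"""

import itertools

import numpy as np


def pi_pairwise_oracle(hap_block, window_length):
    """Average pairwise difference between haplotype rows per bp."""
    n = hap_block.shape[0]
    total = 0
    pairs = 0
    for i, j in itertools.combinations(range(n), 2):
        total += int((hap_block[i] != hap_block[j]).sum())
        pairs += 1
    return total / pairs / window_length


def wc_site_oracle(genotypes_by_pop):
    """Weir & Cockerham (1984) a, b, c for one site.

    ``genotypes_by_pop``: list (one per population) of lists of (a0, a1)
    diploid allele pairs.
    """
    r = len(genotypes_by_pop)
    n = [len(g) for g in genotypes_by_pop]
    p = [sum(a0 + a1 for a0, a1 in g) / (2 * len(g)) for g in genotypes_by_pop]
    h = [sum(1 for a0, a1 in g if a0 != a1) / len(g) for g in genotypes_by_pop]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni**2 for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return a, b, c


def wc_window_fst_oracle(panel, popmap, pops, site_indices):
    """Ratio-of-sums windowed WC FST via the per-site oracle."""
    num = den = 0.0
    for j in site_indices:
        gbp = []
        for pop in pops:
            gts = []
            for s in popmap.samples(pop):
                i = panel.sample_index(s)
                gts.append(
                    (int(panel.haplotypes[2 * i, j]), int(panel.haplotypes[2 * i + 1, j]))
                )
            gbp.append(gts)
        a, b, c = wc_site_oracle(gbp)
        num += a
        den += a + b + c
    return num / den if den else float("nan")


def d_jackknife_oracle(freqs, block_ids):
    """D with delete-one-block jackknife from per-site frequencies.

    ``freqs`` is a (4, S) array of P1, P2, P3, outgroup frequencies.
    """
    p1, p2, p3, p4 = freqs
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    d = (abba - baba).sum() / (abba + baba).sum()
    labels = sorted(set(block_ids.tolist()))
    est = []
    for lab in labels:
        keep = block_ids != lab
        est.append((abba[keep] - baba[keep]).sum() / (abba[keep] + baba[keep]).sum())
    est = np.array(est)
    B = len(labels)
    se = np.sqrt((B - 1) / B * ((est - est.mean()) ** 2).sum())
    return d, se


def f3_oracle(pc, pa, pb, n_c, block_ids):
    per_site = (pc - pa) * (pc - pb) - pc * (1 - pc) / (n_c - 1)
    value = per_site.mean()
    labels = sorted(set(block_ids.tolist()))
    est = [per_site[block_ids != lab].mean() for lab in labels]
    est = np.array(est)
    B = len(labels)
    se = np.sqrt((B - 1) / B * ((est - est.mean()) ** 2).sum())
    return value, se


def u_count_oracle(panel, popmap, source, target, donor, start, end, x, y, w=1.0):
    """Count qualifying SNPs in [start, end) by explicit per-site loop."""

    def freq(pop, j, allele):
        rows = popmap.haplotype_rows(panel, pop)
        return float((panel.haplotypes[rows, j] == allele).mean())

    count = 0
    for j in range(panel.n_sites):
        pos0 = panel.pos[j] - 1
        if not (start <= pos0 < end):
            continue
        for allele in (0, 1):
            if (
                freq(donor, j, allele) == w
                and freq(source, j, allele) < x
                and freq(target, j, allele) > y
            ):
                count += 1
                break
    return count


def ancestry_bitmap_oracle(tract_df, contig_lengths, samples):
    """Per-sample donor fraction by per-bp marking (small contigs only)."""
    genome = sum(contig_lengths.values())
    out = {}
    for s in samples:
        covered = 0
        for hap in (0, 1):
            for contig, length in contig_lengths.items():
                bitmap = np.zeros(length, dtype=bool)
                sel = tract_df[
                    (tract_df["sample"] == s)
                    & (tract_df["hap"] == hap)
                    & (tract_df["contig"] == contig)
                ]
                for row in sel.itertuples(index=False):
                    bitmap[row.start : row.end] = True
                covered += int(bitmap.sum())
        out[s] = covered / (2 * genome)
    return out


def merge_bitmap_oracle(intervals, length):
    """Merged intervals on a single contig via per-bp marking."""
    bitmap = np.zeros(length, dtype=bool)
    for s, e in intervals:
        bitmap[s:e] = True
    merged = []
    start = None
    for i, v in enumerate(bitmap):
        if v and start is None:
            start = i
        elif not v and start is not None:
            merged.append((start, i))
            start = None
    if start is not None:
        merged.append((start, length))
    return merged
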