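"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written as plain loops over the definitions, deliberately
sharing no code with the package internals.
"""

from __future__ import annotations

import itertools

import numpy as np

MISSING = -1


def roh_segments_bruteforce(pos, gt, params):
    """Exhaustive-scan ROH caller.

    Enumerates every window of ``window_snp`` consecutive SNPs, classifies it
    homozygous by explicit counting, computes each SNP's hom-window fraction
    over the windows that actually span it, takes maximal runs of SNPs at or
    above the threshold, splits runs at gaps larger than ``max_gap_kb`` and
    applies the length / SNP-count / density tests.  Returns a list of
    (start, end, n_snps) tuples.
    """
    n = len(pos)
    w = params.window_snp
    if n < w:
        return []
    windows = []
    for start in range(n - w + 1):
        het = sum(1 for k in range(start, start + w) if gt[k] == 1)
        mis = sum(1 for k in range(start, start + w) if gt[k] == MISSING)
        windows.append(het <= params.window_het and mis <= params.window_missing)
    eligible = []
    for i in range(n):
        spanning = [s for s in range(n - w + 1) if s <= i <= s + w - 1]
        hom = sum(1 for s in spanning if windows[s])
        eligible.append(hom / len(spanning) >= params.window_threshold)
    segments = []
    i = 0
    while i < n:
        if not eligible[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and eligible[j + 1]:
            j += 1
        runs = []
        a = i
        for k in range(i, j):
            if (pos[k + 1] - pos[k]) / 1000.0 > params.max_gap_kb:
                runs.append((a, k))
                a = k + 1
        runs.append((a, j))
        for a, b in runs:
            length_kb = (pos[b] - pos[a] + 1) / 1000.0
            n_snps = b - a + 1
            if (
                length_kb >= params.min_kb
                and n_snps >= params.min_snp
                and length_kb / n_snps <= params.density_kb_per_snp
            ):
                segments.append((int(pos[a]), int(pos[b]), n_snps))
        i = j + 1
    return segments


def pi_pairwise_bruteforce(gt_window, span_bp):
    """Mean pairwise difference per bp over all pairs of sample alleles.

    ``gt_window`` is a (sites x samples) 0/1/2/-1 matrix for one population
    and one window.  At each site the called genotypes are expanded into
    alleles and every unordered allele pair is compared; per-site averages
    are summed and divided by the window span.
    """
    total = 0.0
    for row in gt_window:
        alleles = []
        for g in row:
            if g == MISSING:
                continue
            alleles.extend({0: [0, 0], 1: [0, 1], 2: [1, 1]}[int(g)])
        if len(alleles) < 2:
            continue
        diff = 0
        pairs = 0
        for a, b in itertools.combinations(alleles, 2):
            pairs += 1
            diff += a != b
        total += diff / pairs
    return total / span_bp


def sfs_enumeration(m, s, k):
    """Hypergeometric pmf over derived counts 0..k by explicit enumeration
    of allele subsets (feasible for tiny s)."""
    alleles = [1] * m + [0] * (s - m)
    counts = np.zeros(k + 1)
    n_sub = 0
    for combo in itertools.combinations(range(s), k):
        counts[sum(alleles[i] for i in combo)] += 1
        n_sub += 1
    return counts / n_sub


# Grantham (1974) published distance table, transcribed row by row
# (upper triangle; row amino acid first).  Used as the independent oracle
# for the recomputed matrix.
GRANTHAM_1974 = {}
_ROWS = """
S R110 L145 P74 T58 A99 V124 G56 I142 F155 Y144 C112 H89 Q68 N46 K121 D65 E80 M135 W177
R L102 P103 T71 A112 V96 G125 I97 F97 Y77 C180 H29 Q43 N86 K26 D96 E54 M91 W101
L P98 T92 A96 V32 G138 I5 F22 Y36 C198 H99 Q113 N153 K107 D172 E138 M15 W61
P T38 A27 V68 G42 I95 F114 Y110 C169 H77 Q76 N91 K103 D108 E93 M87 W147
T A58 V69 G59 I89 F103 Y92 C149 H47 Q42 N65 K78 D85 E65 M81 W128
A V64 G60 I94 F113 Y112 C195 H86 Q91 N111 K106 D126 E107 M84 W148
V G109 I29 F50 Y55 C192 H84 Q96 N133 K97 D152 E121 M21 W88
G I135 F153 Y147 C159 H98 Q87 N80 K127 D94 E98 M127 W184
I F21 Y33 C198 H94 Q109 N149 K102 D168 E134 M10 W61
F Y22 C205 H100 Q116 N158 K102 D177 E140 M28 W40
Y C194 H83 Q99 N143 K85 D160 E122 M36 W37
C H174 Q154 N139 K202 D154 E170 M196 W215
H Q24 N68 K32 D81 E40 M87 W115
Q N46 K53 D61 E29 M101 W130
N K94 D23 E42 M142 W174
K D101 E56 M95 W110
D E45 M160 W181
E M126 W152
M W67
"""
for _line in _ROWS.strip().splitlines():
    _parts = _line.split()
    _a = _parts[0]
    for _tok in _parts[1:]:
        GRANTHAM_1974[(_a, _tok[0])] = int(_tok[1:])
        GRANTHAM_1974[(_tok[0], _a)] = int(_tok[1:])
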