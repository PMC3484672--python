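"""Independent brute-force oracle for breakpoint decomposition.

Candidate (L, R) pairs are bounded by the common prefix/suffix of product
and amplicon, but every candidate is verified by literal reconstruction,
and the canonical choice is made by explicitly sorting the full list —
independently of the direct construction used by the package.
"""

from os.path import commonprefix


def brute_decompositions(amp: str, prod: str):
    """Every (L, R, insert) with prod == amp[:L] + insert + amp[R:], L < R."""
    if len(prod) >= len(amp):
        return []
    max_l = len(commonprefix([amp, prod]))
    out = []
    for L in range(0, min(max_l, len(prod)) + 1):
        for R in range(L + 1, len(amp) + 1):
            f = len(amp) - R
            if f > len(prod) - L:
                continue
            insert = prod[L : len(prod) - f]
            if amp[:L] + insert + amp[R:] == prod:
                out.append((L, R, insert))
    return out


def canonical_choice(decomps, amp_len):
    """Rightmost-L among minimal-insert, maximal-flank decompositions."""
    assert decomps
    return min(
        decomps,
        key=lambda d: (len(d[2]), -(d[0] + amp_len - d[1]), -d[0]),
    )


def zero_insert_placements(decomps):
    return sorted((L, R) for L, R, ins in decomps if not ins)
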