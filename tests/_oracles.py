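"""Independent reference implementations used only as test oracles."""

from tseen.homology import _CODE, ScoringScheme


def brute_force_local(a: str, b: str, scoring: ScoringScheme) -> int:
    """Exhaustive enumeration of every gapped local alignment between all
    substring start positions; independent of the DP implementation."""
    sub = scoring.substitution_matrix
    go, ge = scoring.gap_open, scoring.gap_extend
    best = 0

    def rec(i, j, state, score):
        nonlocal best
        if score > best:
            best = score
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + sub[_CODE[a[i]], _CODE[b[j]]])
        if i < len(a):
            rec(i + 1, j, "I", score - (ge if state == "I" else go + ge))
        if j < len(b):
            rec(i, j + 1, "D", score - (ge if state == "D" else go + ge))

    for i0 in range(len(a)):
        for j0 in range(len(b)):
            rec(i0, j0, "S", 0)
    return best
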