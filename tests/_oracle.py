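"""Independent brute-force oracles used only by the tests.

The local-alignment oracle is a plain-Python Smith-Waterman over the full
dynamic-programming matrix (no seeding, no windows, no numba), kept
deliberately separate from the package's aligner implementation.
"""

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def sw_score(query: str, subject: str, match: float = 1.0,
             mismatch: float = -2.0, gap: float = 2.5) -> float:
    """Optimal local-alignment score, linear gap cost per gap character."""
    best = 0.0
    prev = [0.0] * (len(subject) + 1)
    for qc in query:
        cur = [0.0]
        for j, sc in enumerate(subject, 1):
            diag = prev[j - 1] + (match if (qc == sc and qc != "N") else mismatch)
            v = max(0.0, diag, prev[j] - gap, cur[j - 1] - gap)
            cur.append(v)
        best = max(best, max(cur))
        prev = cur
    return best


def sw_score_both_strands(query: str, subject: str, **kw) -> float:
    return max(sw_score(query, subject, **kw), sw_score(revcomp(query), subject, **kw))


def has_exact_word(query: str, subject: str, w: int = 28) -> bool:
    """Whether the pair shares an exact w-mer on either strand."""
    words = {query[i:i + w] for i in range(len(query) - w + 1)}
    rc = revcomp(query)
    words |= {rc[i:i + w] for i in range(len(rc) - w + 1)}
    words = {x for x in words if "N" not in x}
    return any(subject[j:j + w] in words for j in range(len(subject) - w + 1))
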