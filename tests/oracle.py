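"""Independent brute-force oracles used only by the tests.

Deliberately naive: explicit loops straight from the definitions, no
vectorisation, no shared code with the package internals.
"""

CHARGE = {"K": 1.0, "R": 1.0, "H": 0.5, "D": -1.0, "E": -1.0}


def charge(aa: str) -> float:
    return CHARGE.get(aa, 0.0)


def brute_alignment_score(cdr3: str, fragment: str, offset: int,
                          w_direct: float = 1.0, w_adjacent: float = 0.5) -> float:
    total = 0.0
    for i, aa in enumerate(cdr3):
        qc = charge(aa)
        for j, w in ((offset + i, w_direct),
                     (offset + i - 1, w_adjacent),
                     (offset + i + 1, w_adjacent)):
            if 0 <= j < len(fragment):
                total += -qc * charge(fragment[j]) * w
    return total


def brute_pair_score(a: str, b: str,
                     w_direct: float = 1.0, w_adjacent: float = 0.5) -> float:
    slider, template = (a, b) if len(a) <= len(b) else (b, a)
    return max(
        brute_alignment_score(slider, template, off, w_direct, w_adjacent)
        for off in range(len(template) - len(slider) + 1)
    )
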