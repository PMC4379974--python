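"""Independent brute-force oracles used to cross-check the implementation."""
from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# standard genetic code, written out independently of the package
_CODE = {}
for _i, _b1 in enumerate("TCAG"):
    for _j, _b2 in enumerate("TCAG"):
        for _k, _b3 in enumerate("TCAG"):
            _CODE[_b1 + _b2 + _b3] = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"[
                16 * _i + 4 * _j + _k
            ]
_STOPS = {c for c, a in _CODE.items() if a == "*"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def translate_brute(seq: str, phase: int = 0) -> str:
    out = []
    for i in range(phase, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append("X" if "N" in codon else _CODE[codon])
    return "".join(out)


def orfs_brute(seq: str, min_aa: int) -> set[tuple]:
    """Every ORF in all six frames, by position scanning.

    Complete ORFs: first ATG after the previous in-frame stop, through the
    next stop. A frame without any complete ORF contributes its trailing
    open stretch (after the last stop, or the whole frame) as a partial ORF.
    Returned as (strand, frame, fwd_start, fwd_end, has_start, has_stop, aa).
    """
    n = len(seq)
    out: set[tuple] = set()
    for strand in "+-":
        s = seq if strand == "+" else rc(seq)
        for f in range(3):
            stops = [i for i in range(f, n - 2, 3) if s[i : i + 3] in _STOPS]
            found_complete = False
            spans = []
            prev_end = f
            for st in stops:
                atg = None
                j = prev_end
                while j < st:
                    if s[j : j + 3] == "ATG":
                        atg = j
                        break
                    j += 3
                if atg is not None:
                    spans.append((atg, st + 3, True, True))
                    found_complete = True
                prev_end = st + 3
            if not found_complete:
                tail = stops[-1] + 3 if stops else f
                last_full = tail + 3 * ((n - tail) // 3)
                if last_full > tail:
                    spans.append(
                        (tail, last_full, s[tail : tail + 3] == "ATG", False)
                    )
            for a, b, hs, he in spans:
                aa = (b - a) // 3 - (1 if he else 0)
                if aa < min_aa:
                    continue
                if strand == "-":
                    a, b = n - b, n - a
                out.add((strand, f, a, b, hs, he, aa))
    return out
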