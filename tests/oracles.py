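"""Independent brute-force oracles used to cross-check the library.

These deliberately avoid the package's rule-table machinery: each
enzyme's specificity is spelled out as a literal per-bond condition, so
agreement with the library is evidence that the generic rule engine
encodes the documented baseline correctly.
"""

from __future__ import annotations


def oracle_cut_sites(sequence: str, enzyme_code: str) -> list[int]:
    """Bond-by-bond cleavage test with hard-coded baseline rules."""
    sites = []
    for i in range(1, len(sequence)):  # bond between residues i and i+1
        p1, p1p = sequence[i - 1], sequence[i]
        if enzyme_code == "TR":
            cut = p1 in "KR" and p1p != "P"
        elif enzyme_code == "CTR":
            cut = p1 in "FLMWY" and p1p != "P"
        elif enzyme_code == "PEP":
            cut = p1 in "FL" and p1p != "P"
        elif enzyme_code == "LysC":
            cut = p1 == "K"
        elif enzyme_code == "PROK":
            cut = p1 in "AEFILTVWY"
        elif enzyme_code == "TLN":
            cut = p1p in "AFILMV" and p1 != "P"
        else:
            raise ValueError(enzyme_code)
        if cut:
            sites.append(i)
    return sites


def oracle_fragments(sequence: str, enzyme_codes) -> list[tuple[str, int]]:
    """Fragments between the union of per-enzyme oracle cut sites."""
    sites = sorted({s for code in enzyme_codes for s in oracle_cut_sites(sequence, code)})
    bounds = [0, *sites, len(sequence)]
    return [(sequence[a:b], a + 1) for a, b in zip(bounds[:-1], bounds[1:])]


def oracle_substring_positions(needle: str, haystack: str) -> list[int]:
    """Quadratic sliding-window exact-match scan (1-based positions)."""
    return [
        p + 1
        for p in range(len(haystack) - len(needle) + 1)
        if haystack[p : p + len(needle)] == needle
    ]
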