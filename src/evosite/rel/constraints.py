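"""Constrained reversible nucleotide models: exchangeability-sharing schemes.

The five relative exchangeabilities {AC, AT, CG, CT, GT} are expressed against
the A<->G reference rate (fixed at 1).  Each slot is either the literal
reference ("ref") or the name of a shared free parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

REF = "ref"
_PAIRS = ("AC", "AT", "CG", "CT", "GT")


@dataclass(frozen=True)
class NucleotideConstraintSet:
    name: str
    slots: dict[str, str]  # pair -> "ref" or free-parameter name

    def __post_init__(self):
        if set(self.slots) != set(_PAIRS):
            raise ValueError(f"constraint set must assign exactly {_PAIRS}")
        if not self.free_parameters() and any(v != REF for v in self.slots.values()):
            raise ValueError("inconsistent slots")

    def free_parameters(self) -> list[str]:
        seen = []
        for pair in _PAIRS:
            v = self.slots[pair]
            if v != REF and v not in seen:
                seen.append(v)
        return seen

    def rates(self, values: dict[str, float]) -> dict[str, float]:
        """Expand free-parameter values into the full pair->rate mapping
        (AG reference = 1 implied)."""
        out = {}
        for pair in _PAIRS:
            v = self.slots[pair]
            out[pair] = 1.0 if v == REF else float(values[v])
        out["AG"] = 1.0
        return out


#: Published per-gene schemes (free parameters named after the pair that
#: introduces them; ties share a name).
CHIJ = NucleotideConstraintSet("chiJ", {
    "AC": "R_AC", "AT": "R_AT", "CG": REF, "CT": "R_AC", "GT": "R_AT"})
RECA = NucleotideConstraintSet("recA", {
    "AC": REF, "AT": REF, "CG": "R_CG", "CT": "R_CT", "GT": "R_GT"})
# the CT slot is not stated for dnaN; modelled as its own free parameter
DNAN = NucleotideConstraintSet("dnaN", {
    "AC": REF, "AT": REF, "CG": "R_CG", "CT": "R_CT", "GT": REF})
EQUAL_RATES = NucleotideConstraintSet("equal", {p: REF for p in _PAIRS})
FULL_GTR = NucleotideConstraintSet("gtr", {p: f"R_{p}" for p in _PAIRS})

PRESETS = {c.name: c for c in (CHIJ, RECA, DNAN, EQUAL_RATES, FULL_GTR)}


def constraint_set_from_dict(name: str, slots: dict[str, str]) -> NucleotideConstraintSet:
    return NucleotideConstraintSet(name, dict(slots))
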