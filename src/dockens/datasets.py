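"""Small literature-derived example datasets.

These are the published benchmark inputs both protocols are typically run
on: amyloidogenic peptide sequences of deposited protofilament structures,
and aspartate-protease substrate peptides annotated with their
experimentally determined cleavage position (an em-dash marks the scissile
bond, e.g. ``KPAEF—IRL`` is cleaved at peptide bond 5).
"""

from __future__ import annotations

from .structio import parse_annotated_substrate

#: Amyloidogenic peptide sequences of experimentally solved protofilaments,
#: keyed by the PDB id of the deposited structure, with the number of chains
#: in the deposition.
AMYLOID_PEPTIDES: dict[str, tuple[str, int]] = {
    "2E8D": ("SNFLNCYVSGFHPSDIEVDLLK", 4),   # beta2-microglobulin fragment
    "2NNT": ("MGATAVSEWTEYKTADGKTFYYNNRTLESTW", 4),  # CA150.WW2
    "6TI5": ("EVHHQKLVFFAEDVGSNKGAIIGLMVGGVV", 6),   # Aβ40
    "6ZRQ": ("FLVHSGNNFGAILSSTNVGSNTY", 8),  # amylin S20G
    "7YAT": ("GAVVGGLGGYMLGSAMSRPMMHFGN", 6),  # hamster prion 108-144 fragment
    "7Q66": ("TGTANTLFGTASTGTSLFSSQNNAF", 11),  # Nup98 FG-repeat fragment
}

#: Annotated substrate peptides of three aspartate proteases, in benchmark
#: order: (enzyme, annotated sequence). The em-dash marks the experimentally
#: determined cleavage site.
PROTEASE_SUBSTRATES: list[tuple[str, str]] = [
    ("pepsin", "KPAEF—IRL"),
    ("pepsin", "HPHLSF—MAI"),
    ("pepsin", "AFPLEF—IREL"),
    ("pepsin", "ENESAEAFPLEF—IRELEGER"),
    ("pepsin", "TMARHPHPHLSF—MAIPPKKNQ"),
    ("renin", "PFHL—LVYS"),
    ("renin", "PYIL—KRGS"),
    ("renin", "DRVYIHPFHL—VIHNESTC"),
    ("HIV-1", "GAETF—YVDGA"),
    ("HIV-1", "IRKIL—FLDGI"),
    ("HIV-1", "TEPISGAETF—YVDGA"),
    ("HIV-1", "GAETF—YVDGAANRET"),
    ("HIV-1", "AAGAVASYDY—LVIGGG"),
    ("HIV-1", "SYFNLNPFEVL—QIDPE"),
    ("HIV-1", "NVVNSGGMVM—MVPGAG"),
]


def substrate_table() -> list[dict]:
    """Parsed benchmark substrates: enzyme, sequence, 1-based scissile bond."""
    rows = []
    for number, (enzyme, annotated) in enumerate(PROTEASE_SUBSTRATES, start=1):
        sequence, bond = parse_annotated_substrate(annotated)
        rows.append({
            "number": number, "enzyme": enzyme, "annotated": annotated,
            "sequence": sequence, "scissile_bond": bond,
        })
    return rows
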