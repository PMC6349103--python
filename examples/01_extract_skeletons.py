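"""Extract carbon skeletons from diterpenoid structures.

Parses a few classic Lamiaceae diterpenoids from SMILES, applies the
saturate-and-fragment rule (all bonds to single, carbon-heteroatom bonds
broken, fragment closest to 20 carbons kept) and matches the result
against the shipped reference skeleton library.
"""

from skeletax import (
    CompoundRecord,
    assignments_table,
    default_library,
    extract_skeleton,
    parse_structure,
    standardize,
)

COMPOUNDS = {
    # sclareol: a labdane diol from Salvia sclarea
    "sclareol": "CC1(C)CCCC2(C)C1CCC(C)(O)C2CCC(C)(O)C=C",
    # an acetylated, glycosylated labdanoid: decorations add carbon-bearing
    # fragments (C2 acyl, C6 sugar) that must not displace the C20 core
    "labdanoid ester glycoside": (
        "CC1(C)CCCC2(C)C1CCC(C)(OC(C)=O)C2CCC(C)(C=C)"
        "OC1OC(CO)C(O)C(O)C1O"
    ),
    # carnosic acid-like abietane diphenol (aromatic C ring)
    "abietane diphenol": (
        "CC(C)c1cc2c(c(O)c1O)C1(CCCC(C)(C)C1CC2)C(=O)O"
    ),
}

library = default_library()
assignments = []
for name, smiles in COMPOUNDS.items():
    record = CompoundRecord(
        compound_id=name,
        structure_text=smiles,
        graph=standardize(parse_structure(smiles, "smiles")),
    )
    assignments.append(extract_skeleton(record, library))

print(assignments_table(assignments).to_string(index=False))
print()
print(
    "Each row shows the canonical skeleton ID (a SMILES of the saturated\n"
    "carbon core), the core's carbon count, and the reference skeleton it\n"
    "is isomorphic to; fragment_carbon_counts lists every carbon fragment\n"
    "the molecule broke into (esters and sugars appear as small fragments\n"
    "that lose to the C20 core)."
)
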