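"""Compound and measurement vocabulary for archaeal ether lipid analysis.

The analytes are the isoprenoid glycerol dialkyl glycerol tetraethers (GDGTs)
with 0-3 cyclopentane rings, crenarchaeol (4 cyclopentane + 1 cyclohexane
ring) and its late-eluting regioisomer, and the diether archeol. The C46
glycerol trialkyl glycerol tetraether is a synthetic internal standard spiked
into every extract; it is never reported as an analyte.
"""

GDGT_0 = "GDGT-0"
GDGT_1 = "GDGT-1"
GDGT_2 = "GDGT-2"
GDGT_3 = "GDGT-3"
CRENARCHAEOL = "crenarchaeol"
CRENARCHAEOL_ISOMER = "crenarchaeol-isomer"
ARCHEOL = "archeol"
INTERNAL_STANDARD = "C46-standard"

#: Quantified analytes, in reporting order.
ANALYTES = (
    GDGT_0,
    GDGT_1,
    GDGT_2,
    GDGT_3,
    CRENARCHAEOL,
    CRENARCHAEOL_ISOMER,
    ARCHEOL,
)

#: Tetraether analytes (everything except the diether archeol).
GDGTS = ANALYTES[:6]

#: Cyclopentane ring count per tetraether (crenarchaeol additionally carries
#: one cyclohexane ring; archeol has no rings and no entry here).
CYCLOPENTANE_RINGS = {
    GDGT_0: 0,
    GDGT_1: 1,
    GDGT_2: 2,
    GDGT_3: 3,
    CRENARCHAEOL: 4,
    CRENARCHAEOL_ISOMER: 4,
}

FRACTIONS = ("hydrolyzed", "non_hydrolyzed")

#: Head-group classes. "core" is the bare lipid; MH/DH/PH/HPH are the
#: mono-hexose, di-hexose, phospho-hexose and hexose-phosphohexose intact
#: polar forms seen only in the non-hydrolyzed fraction.
HEADGROUP_CLASSES = ("core", "MH", "DH", "PH", "HPH")
IPL_CLASSES = ("MH", "DH", "PH", "HPH")

ADDUCTS = ("M+NH4", "M+Na", "M+H")


def is_gdgt(compound: str) -> bool:
    return compound in GDGTS
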