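"""Canonical labels for the phylotypes that define the sub-CST naming rules."""

L_CRISPATUS = "Lactobacillus_crispatus"
L_INERS = "Lactobacillus_iners"
L_GASSERI = "Lactobacillus_gasseri"
L_JENSENII = "Lactobacillus_jensenii"
G_VAGINALIS = "Gardnerella_vaginalis"
#: Candidatus Lachnocurva vaginae (formerly BVAB1); genus-rank label.
CA_L_VAGINAE = "g_Lachnocurva"
A_VAGINAE = "Atopobium_vaginae"
PREVOTELLA = "Prevotella_bivia"
STREPTOCOCCUS = "g_Streptococcus"
ENTEROCOCCUS = "g_Enterococcus"
BIFIDOBACTERIUM = "g_Bifidobacterium"
STAPHYLOCOCCUS = "g_Staphylococcus"

#: The twelve key taxa whose mean abundances characterize the 13 sub-CSTs.
KEY_TAXA = (
    L_CRISPATUS,
    L_INERS,
    L_GASSERI,
    L_JENSENII,
    G_VAGINALIS,
    CA_L_VAGINAE,
    A_VAGINAE,
    PREVOTELLA,
    STREPTOCOCCUS,
    ENTEROCOCCUS,
    BIFIDOBACTERIUM,
    STAPHYLOCOCCUS,
)

#: Marker genus -> IV-C subtype suffix for the diverse, Lactobacillus-
#: deficient communities (the even/Prevotella subtype C0 is the fallback).
IVC_MARKERS = {
    STREPTOCOCCUS: "IV-C1",
    ENTEROCOCCUS: "IV-C2",
    BIFIDOBACTERIUM: "IV-C3",
    STAPHYLOCOCCUS: "IV-C4",
}
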