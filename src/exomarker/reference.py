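"""Bundled reference marker panel.

A published discovery-cohort summary of 37 urinary-exosome prostate-cancer
biomarker candidates (15 controls, 16 patients): per-protein detection
counts in each group, the number of patients positive at the
full-specificity threshold, the validated pooled-iBAQ patient:control
ratio, and abundance as ppm of the total proteome.  The panel serves as a
worked example and regression fixture for the marker-evaluation arithmetic;
it contains summary counts only, not per-sample quantifications.
"""

from __future__ import annotations

import pandas as pd

_PANEL_ROWS = [
    # accession, protein_name, ctr_present(/15), pat_present(/16),
    # pat_positive at 100% specificity, iBAQ ratio PAT:CTR, abundance ppm
    ("Q8N2U0", "Transmembrane protein 256", 5, 16, 15, 140.39, 4324),
    ("Q15847", "Adipogenesis regulatory factor", 4, 15, 13, 18.99, 369),
    ("Q6IAA8", "Ragulator complex protein LAMTOR1", 4, 16, 13, 22.98, 201),
    ("P13796", "Plastin-2", 14, 16, 12, 3.15, 256),
    ("P61019", "Ras-related protein Rab-2A", 14, 16, 12, 3.55, 1083),
    ("P20337", "Ras-related protein Rab-3B", 15, 16, 12, 2.69, 1138),
    ("O95716", "Ras-related protein Rab-3D", 15, 16, 12, 2.24, 2340),
    ("P51149", "Ras-related protein Rab-7a", 15, 16, 12, 3.26, 2317),
    ("P27449", "V-type proton ATPase 16 kDa proteolipid subunit",
     0, 12, 12, 3.55, 861),
    ("Q687X5", "Metalloreductase STEAP4", 14, 16, 11, 2.97, 953),
    ("Q99497", "Protein DJ-1", 15, 16, 11, 1.92, 957),
    ("P25815", "Protein S100-P", 14, 15, 11, 1.84, 1351),
    ("Q96C24", "Synaptotagmin-like protein 4", 5, 12, 11, 3.08, 91),
    ("Q9NVJ2", "ADP-ribosylation factor-like protein 8B", 13, 15, 10, 2.79, 49),
    ("Q96QE2", "Proton myo-inositol cotransporter", 2, 11, 10, 2.66, 100),
    ("P20340", "Ras-related protein Rab-6A", 10, 16, 10, 3.36, 240),
    ("O43657", "Tetraspanin-6", 9, 16, 10, 4.03, 3067),
    ("P78369", "Claudin-10", 7, 14, 9, 2.14, 26),
    ("P57739", "Claudin-2", 2, 12, 9, 3.00, 69),
    ("O15551", "Claudin-3", 1, 10, 9, 1.75, 170),
    ("O60547", "GDP-mannose 4,6 dehydratase", 2, 12, 9, 2.45, 16),
    ("P46926", "Glucosamine-6-phosphate isomerase 1", 4, 13, 9, 15.51, 44),
    ("Q14108", "Lysosome membrane protein 2", 15, 16, 9, 3.94, 824),
    ("Q6NUT3", "Major facilitator superfamily domain-containing protein 12",
     5, 15, 9, 8.07, 65),
    ("Q9BV36", "Melanophilin", 12, 16, 9, 2.26, 151),
    ("P35270", "Sepiapterin reductase", 10, 14, 9, 2.16, 114),
    ("Q9BRA2", "Thioredoxin domain-containing protein 17", 15, 16, 9, 2.35, 288),
    ("Q9BUT1", "3-hydroxybutyrate dehydrogenase type 2", 14, 16, 8, 2.26, 389),
    ("P62158", "Calmodulin", 15, 16, 8, 6.30, 4764),
    ("Q9Y646", "Carboxypeptidase Q", 1, 8, 8, 5.80, 51),
    ("Q14254", "Flotillin-2", 14, 16, 8, 2.89, 541),
    ("Q08380", "Galectin-3-binding protein", 15, 16, 8, 1.99, 678),
    ("Q99571", "P2X purinoceptor 4", 6, 13, 8, 2.36, 76),
    ("Q9Y3R5", "Protein dopey-2", 12, 16, 8, 2.99, 218),
    ("P06703", "Protein S100-A6", 15, 16, 8, 0.48, 1853),
    ("Q15286", "Ras-related protein Rab-35", 15, 16, 8, 0.57, 245),
    ("P67775",
     "Serine/threonine-protein phosphatase 2A catalytic subunit alpha isoform",
     11, 14, 8, 16.91, 41),
]

N_CONTROL = 15
N_PATIENT = 16


def focus_candidates_panel() -> pd.DataFrame:
    """The 37-candidate reference panel as a DataFrame indexed by accession."""
    df = pd.DataFrame(_PANEL_ROWS, columns=[
        "protein_accession", "protein_name", "ctr_present", "pat_present",
        "pat_positive", "ibaq_ratio", "abundance_ppm",
    ])
    return df.set_index("protein_accession")
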