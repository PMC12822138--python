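"""Canonical region-of-interest vocabulary.

The analysis operates on 41 hemisphere-averaged grey-matter measures: 34
cortical thicknesses (Desikan–Killiany parcellation, mm) and 7 subcortical
volumes (mm^3).  Every module refers to regions through the canonical names
defined here; the reader maps vendor column layouts onto them.
"""

from __future__ import annotations

#: 34 Desikan–Killiany cortical parcels (thickness, mm).
CORTICAL_ROIS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

#: 7 subcortical structures (volume, mm^3).
SUBCORTICAL_ROIS: tuple[str, ...] = (
    "hippocampus",
    "thalamus",
    "amygdala",
    "putamen",
    "pallidum",
    "accumbens",
    "caudate",
)

#: Full 41-region feature vocabulary in canonical order.
ALL_ROIS: tuple[str, ...] = CORTICAL_ROIS + SUBCORTICAL_ROIS

N_CORTICAL = len(CORTICAL_ROIS)
N_SUBCORTICAL = len(SUBCORTICAL_ROIS)
N_ROIS = len(ALL_ROIS)

#: Cortical signature of AD-typical neurodegeneration: temporal-lobe parcels
#: whose thinning tracks Alzheimer-type atrophy.
AD_SIGNATURE_ROIS: tuple[str, ...] = (
    "entorhinal",
    "inferiortemporal",
    "middletemporal",
    "fusiform",
)

#: Cortical signature of brain resilience.  The parcellation splits the
#: anterior cingulate into rostral and caudal labels, so "anterior cingulate
#: and temporal pole" resolves to three parcels by default (configurable).
RESILIENCE_SIGNATURE_ROIS: tuple[str, ...] = (
    "rostralanteriorcingulate",
    "caudalanteriorcingulate",
    "temporalpole",
)

#: The three most discriminative cortical regions between clusters, carried
#: forward as longitudinal outcomes.
DISCRIMINATIVE_ROIS: tuple[str, ...] = (
    "superiorfrontal",
    "superiorparietal",
    "supramarginal",
)

#: Cognitive domains of the test battery, canonical order.
COGNITIVE_DOMAINS: tuple[str, ...] = (
    "episodic_memory",
    "attention_speed",
    "executive_function",
    "verbal_fluency",
    "visuospatial",
)

assert N_ROIS == 41
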