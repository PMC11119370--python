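"""AAL-90 cerebral parcellation labels.

The automated anatomical labeling (AAL) atlas divides the cerebrum into 90
named regions (45 per hemisphere, odd indices left / even indices right in
1-based atlas numbering). Region order matches the standard AAL numbering,
so e.g. ``Cingulum_Mid_L`` is atlas ID 33 and ``Temporal_Inf_R`` is 90.
"""

from __future__ import annotations

AAL90_LABELS: tuple[str, ...] = (
    "Precentral_L", "Precentral_R",
    "Frontal_Sup_L", "Frontal_Sup_R",
    "Frontal_Sup_Orb_L", "Frontal_Sup_Orb_R",
    "Frontal_Mid_L", "Frontal_Mid_R",
    "Frontal_Mid_Orb_L", "Frontal_Mid_Orb_R",
    "Frontal_Inf_Oper_L", "Frontal_Inf_Oper_R",
    "Frontal_Inf_Tri_L", "Frontal_Inf_Tri_R",
    "Frontal_Inf_Orb_L", "Frontal_Inf_Orb_R",
    "Rolandic_Oper_L", "Rolandic_Oper_R",
    "Supp_Motor_Area_L", "Supp_Motor_Area_R",
    "Olfactory_L", "Olfactory_R",
    "Frontal_Sup_Medial_L", "Frontal_Sup_Medial_R",
    "Frontal_Med_Orb_L", "Frontal_Med_Orb_R",
    "Rectus_L", "Rectus_R",
    "Insula_L", "Insula_R",
    "Cingulum_Ant_L", "Cingulum_Ant_R",
    "Cingulum_Mid_L", "Cingulum_Mid_R",
    "Cingulum_Post_L", "Cingulum_Post_R",
    "Hippocampus_L", "Hippocampus_R",
    "ParaHippocampal_L", "ParaHippocampal_R",
    "Amygdala_L", "Amygdala_R",
    "Calcarine_L", "Calcarine_R",
    "Cuneus_L", "Cuneus_R",
    "Lingual_L", "Lingual_R",
    "Occipital_Sup_L", "Occipital_Sup_R",
    "Occipital_Mid_L", "Occipital_Mid_R",
    "Occipital_Inf_L", "Occipital_Inf_R",
    "Fusiform_L", "Fusiform_R",
    "Postcentral_L", "Postcentral_R",
    "Parietal_Sup_L", "Parietal_Sup_R",
    "Parietal_Inf_L", "Parietal_Inf_R",
    "SupraMarginal_L", "SupraMarginal_R",
    "Angular_L", "Angular_R",
    "Precuneus_L", "Precuneus_R",
    "Paracentral_Lobule_L", "Paracentral_Lobule_R",
    "Caudate_L", "Caudate_R",
    "Putamen_L", "Putamen_R",
    "Pallidum_L", "Pallidum_R",
    "Thalamus_L", "Thalamus_R",
    "Heschl_L", "Heschl_R",
    "Temporal_Sup_L", "Temporal_Sup_R",
    "Temporal_Pole_Sup_L", "Temporal_Pole_Sup_R",
    "Temporal_Mid_L", "Temporal_Mid_R",
    "Temporal_Pole_Mid_L", "Temporal_Pole_Mid_R",
    "Temporal_Inf_L", "Temporal_Inf_R",
)

#: 0-based indices of the eight regions with significantly altered average
#: controllability in the emulated study design (atlas IDs
#: 33, 40, 59, 69, 70, 77, 78, 90).
DEFAULT_EFFECT_REGIONS: tuple[int, ...] = (32, 39, 58, 68, 69, 76, 77, 89)


def default_labels(n_regions: int) -> list[str]:
    """Region labels for an ``n_regions``-node network.

    Returns the AAL-90 names when ``n_regions`` is 90, otherwise generic
    ``ROI_001 ...`` placeholders.
    """
    if n_regions == len(AAL90_LABELS):
        return list(AAL90_LABELS)
    return [f"ROI_{i + 1:03d}" for i in range(n_regions)]


def atlas_id(index: int) -> int:
    """1-based atlas ID for a 0-based region index."""
    return index + 1
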