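"""AAL-90 cerebral parcellation labels.

Only the ordered label list is shipped: nodes of every connectivity matrix in
this package follow this order.  Geometry, MNI coordinates and registration
are out of scope.
"""

from __future__ import annotations

_AAL_REGIONS = (
    "Precentral",
    "Frontal_Sup",
    "Frontal_Sup_Orb",
    "Frontal_Mid",
    "Frontal_Mid_Orb",
    "Frontal_Inf_Oper",
    "Frontal_Inf_Tri",
    "Frontal_Inf_Orb",
    "Rolandic_Oper",
    "Supp_Motor_Area",
    "Olfactory",
    "Frontal_Sup_Medial",
    "Frontal_Med_Orb",
    "Rectus",
    "Insula",
    "Cingulum_Ant",
    "Cingulum_Mid",
    "Cingulum_Post",
    "Hippocampus",
    "ParaHippocampal",
    "Amygdala",
    "Calcarine",
    "Cuneus",
    "Lingual",
    "Occipital_Sup",
    "Occipital_Mid",
    "Occipital_Inf",
    "Fusiform",
    "Postcentral",
    "Parietal_Sup",
    "Parietal_Inf",
    "SupraMarginal",
    "Angular",
    "Precuneus",
    "Paracentral_Lobule",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Thalamus",
    "Heschl",
    "Temporal_Sup",
    "Temporal_Pole_Sup",
    "Temporal_Mid",
    "Temporal_Pole_Mid",
    "Temporal_Inf",
)

#: 90 region labels, left/right interleaved in standard AAL order.
AAL90_LABELS: tuple[str, ...] = tuple(
    f"{name}_{side}" for name in _AAL_REGIONS for side in ("L", "R")
)


def label_index(label: str) -> int:
    """Return the node index of an AAL-90 label."""
    try:
        return AAL90_LABELS.index(label)
    except ValueError:
        raise KeyError(f"unknown AAL-90 label: {label!r}") from None
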