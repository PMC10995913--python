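"""Canonical region index: 148 Destrieux cortical labels + 21 aseg structures.

The index order is fixed and shared by every table in the package:
left-hemisphere cortical regions (Destrieux label order), then
right-hemisphere cortical regions, then subcortical structures.  Cortical
features are FreeSurfer ``aparc.a2009s`` average thicknesses (mm); the
subcortical features are ``aseg`` volumes (mm^3).

The Destrieux atlas defines 74 labels per hemisphere.  The particular set
of 21 subcortical structures is a convention of this package (bilateral
deep grey structures and ventricles plus three midline structures), since
different studies make slightly different choices from the aseg table.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

CORTICAL_KIND = "cortical_thickness"
SUBCORTICAL_KIND = "subcortical_volume"

#: The 74 Destrieux (aparc.a2009s) cortical labels, in FreeSurfer stats-file order.
DESTRIEUX_LABELS: tuple[str, ...] = (
    "G_and_S_frontomargin",
    "G_and_S_occipital_inf",
    "G_and_S_paracentral",
    "G_and_S_subcentral",
    "G_and_S_transv_frontopol",
    "G_and_S_cingul-Ant",
    "G_and_S_cingul-Mid-Ant",
    "G_and_S_cingul-Mid-Post",
    "G_cingul-Post-dorsal",
    "G_cingul-Post-ventral",
    "G_cuneus",
    "G_front_inf-Opercular",
    "G_front_inf-Orbital",
    "G_front_inf-Triangul",
    "G_front_middle",
    "G_front_sup",
    "G_Ins_lg_and_S_cent_ins",
    "G_insular_short",
    "G_occipital_middle",
    "G_occipital_sup",
    "G_oc-temp_lat-fusifor",
    "G_oc-temp_med-Lingual",
    "G_oc-temp_med-Parahip",
    "G_orbital",
    "G_pariet_inf-Angular",
    "G_pariet_inf-Supramar",
    "G_parietal_sup",
    "G_postcentral",
    "G_precentral",
    "G_precuneus",
    "G_rectus",
    "G_subcallosal",
    "G_temp_sup-G_T_transv",
    "G_temp_sup-Lateral",
    "G_temp_sup-Plan_polar",
    "G_temp_sup-Plan_tempo",
    "G_temporal_inf",
    "G_temporal_middle",
    "Lat_Fis-ant-Horizont",
    "Lat_Fis-ant-Vertical",
    "Lat_Fis-post",
    "Pole_occipital",
    "Pole_temporal",
    "S_calcarine",
    "S_central",
    "S_cingul-Marginalis",
    "S_circular_insula_ant",
    "S_circular_insula_inf",
    "S_circular_insula_sup",
    "S_collat_transv_ant",
    "S_collat_transv_post",
    "S_front_inf",
    "S_front_middle",
    "S_front_sup",
    "S_interm_prim-Jensen",
    "S_intrapariet_and_P_trans",
    "S_oc_middle_and_Lunatus",
    "S_oc_sup_and_transversal",
    "S_occipital_ant",
    "S_oc-temp_lat",
    "S_oc-temp_med_and_Lingual",
    "S_orbital_lateral",
    "S_orbital_med-olfact",
    "S_orbital-H_Shaped",
    "S_parieto_occipital",
    "S_pericallosal",
    "S_postcentral",
    "S_precentral-inf-part",
    "S_precentral-sup-part",
    "S_suborbital",
    "S_subparietal",
    "S_temporal_inf",
    "S_temporal_sup",
    "S_temporal_transverse",
)

#: (aseg structure name, hemisphere) pairs for the 21 subcortical features.
ASEG_STRUCTURES: tuple[tuple[str, str], ...] = (
    ("Left-Lateral-Ventricle", "left"),
    ("Left-Thalamus-Proper", "left"),
    ("Left-Caudate", "left"),
    ("Left-Putamen", "left"),
    ("Left-Pallidum", "left"),
    ("Left-Hippocampus", "left"),
    ("Left-Amygdala", "left"),
    ("Left-Accumbens-area", "left"),
    ("Left-VentralDC", "left"),
    ("Right-Lateral-Ventricle", "right"),
    ("Right-Thalamus-Proper", "right"),
    ("Right-Caudate", "right"),
    ("Right-Putamen", "right"),
    ("Right-Pallidum", "right"),
    ("Right-Hippocampus", "right"),
    ("Right-Amygdala", "right"),
    ("Right-Accumbens-area", "right"),
    ("Right-VentralDC", "right"),
    ("Brain-Stem", "midline"),
    ("3rd-Ventricle", "midline"),
    ("4th-Ventricle", "midline"),
)


@dataclass(frozen=True)
class Region:
    """One entry of the canonical feature index."""

    name: str
    hemisphere: str  # left | right | midline
    kind: str  # cortical_thickness | subcortical_volume

    @property
    def units(self) -> str:
        return "mm" if self.kind == CORTICAL_KIND else "mm^3"


@lru_cache(maxsize=1)
def default_region_index() -> tuple[Region, ...]:
    """The canonical ordered index of 169 regions.

    Order: 74 left-hemisphere cortical, 74 right-hemisphere cortical,
    21 subcortical.
    """
    regions: list[Region] = []
    for hemi, prefix in (("left", "lh"), ("right", "rh")):
        for label in DESTRIEUX_LABELS:
            regions.append(Region(f"{prefix}_{label}", hemi, CORTICAL_KIND))
    for name, hemi in ASEG_STRUCTURES:
        regions.append(Region(name, hemi, SUBCORTICAL_KIND))
    names = [r.name for r in regions]
    assert len(names) == len(set(names)) == 169
    return tuple(regions)


def region_names() -> list[str]:
    """Canonical region column names, in index order."""
    return [r.name for r in default_region_index()]


N_REGIONS = 169
N_CORTICAL = 148
N_SUBCORTICAL = 21
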