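"""Cerebellar parcellation schemes.

Two ROI label sets are shipped: a 26-region anatomical scheme following the
AAL3 cerebellar subdivision (hemispheric lobules plus vermal segments) and a
17-region functional scheme following the Buckner resting-state network
parcellation of the cerebellum. Only label lists are shipped — no atlas
volumes; the pipeline operates on ROI-level time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ParcellationSpec:
    """An ordered, named set of ROI labels.

    Parameters
    ----------
    name : str
        Identifier for the scheme (e.g. ``"anatomical26"``).
    roi_labels : tuple of str
        Ordered, unique ROI names. Order fixes row/column order of every
        connectivity matrix built under this scheme.
    """

    name: str
    roi_labels: tuple = field(default_factory=tuple)

    def __post_init__(self):
        labels = tuple(self.roi_labels)
        object.__setattr__(self, "roi_labels", labels)
        if len(set(labels)) != len(labels):
            raise ValueError("ROI labels must be unique")
        if not labels:
            raise ValueError("parcellation needs at least one ROI")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    def index_of(self, label: str) -> int:
        try:
            return self.roi_labels.index(label)
        except ValueError:
            raise KeyError(f"ROI label {label!r} not in parcellation {self.name!r}") from None


# AAL3-style cerebellar subdivision: 9 hemispheric lobules x 2 sides + 8 vermal segments.
_ANATOMICAL26 = (
    "Cerebellum_Crus1_L", "Cerebellum_Crus1_R",
    "Cerebellum_Crus2_L", "Cerebellum_Crus2_R",
    "Cerebellum_3_L", "Cerebellum_3_R",
    "Cerebellum_4_5_L", "Cerebellum_4_5_R",
    "Cerebellum_6_L", "Cerebellum_6_R",
    "Cerebellum_7b_L", "Cerebellum_7b_R",
    "Cerebellum_8_L", "Cerebellum_8_R",
    "Cerebellum_9_L", "Cerebellum_9_R",
    "Cerebellum_10_L", "Cerebellum_10_R",
    "Vermis_1_2", "Vermis_3", "Vermis_4_5", "Vermis_6",
    "Vermis_7", "Vermis_8", "Vermis_9", "Vermis_10",
)

# Buckner 17-network functional parcellation of the cerebellum.
_FUNCTIONAL17 = (
    "Visual-A", "Visual-B",
    "Somatomotor-A", "Somatomotor-B",
    "DorsalAttention-A", "DorsalAttention-B",
    "Salience-A", "Salience-B",
    "Limbic-A", "Limbic-B",
    "Control-A", "Control-B", "Control-C",
    "Default-A", "Default-B", "Default-C",
    "TemporoParietal",
)


def anatomical26() -> ParcellationSpec:
    """26-ROI anatomical cerebellar parcellation (AAL3-style labels)."""
    return ParcellationSpec("anatomical26", _ANATOMICAL26)


def functional17() -> ParcellationSpec:
    """17-ROI functional cerebellar parcellation (Buckner network labels)."""
    return ParcellationSpec("functional17", _FUNCTIONAL17)


_DEFAULTS = {"anatomical26": anatomical26, "functional17": functional17}


def get_parcellation(name: str) -> ParcellationSpec:
    """Look up a shipped parcellation by name."""
    try:
        return _DEFAULTS[name]()
    except KeyError:
        raise KeyError(
            f"unknown parcellation {name!r}; shipped schemes: {sorted(_DEFAULTS)}"
        ) from None


#: Default "affected" node per shipped scheme: the regions the patient group's
#: connectivity is weakened around in the simulation (vermal lobule VIII for the
#: anatomical scheme, the Control-A network for the functional one).
DEFAULT_AFFECTED = {"anatomical26": ("Vermis_8",), "functional17": ("Control-A",)}
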