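"""Parcellation configurations for the targeted (49-node) and whole-brain
(526-node) analyses.

Only the node *counts* and grouping structure are normative: 33 cortical
networks + 10 subcortical regions + 5 brainstem regions + 1 aggregate
cerebellum = 49 targeted nodes; 400 cortical parcels + 62 subcortical +
54 brainstem + 10 cerebellar parcels = 526 whole-brain nodes.  Labels are
editable placeholders; atlas image handling is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ParcellationNode:
    label: str
    source_atlas: str      # cortical-400 | subcortex-62 | brainstem-54 | cerebellum-mdtb
    grouping: str          # cortical | subcortical | brainstem | cerebellum
    hemisphere: str        # left | right | midline | none


@dataclass
class ParcellationConfig:
    name: str
    nodes: list[ParcellationNode]

    @property
    def node_labels(self) -> list[str]:
        return [n.label for n in self.nodes]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def validate(self, expected_count: int | None = None) -> "ParcellationConfig":
        labels = self.node_labels
        if len(set(labels)) != len(labels):
            raise ValueError(f"parcellation {self.name!r}: duplicate node labels")
        if expected_count is not None and len(labels) != expected_count:
            raise ValueError(
                f"parcellation {self.name!r}: {len(labels)} nodes, expected {expected_count}"
            )
        return self


_BRAINSTEM_5 = (
    "nucleus-tractus-solitarii",
    "locus-coeruleus",
    "periaqueductal-grey",
    "ventral-tegmental-area",
    "median-raphe",
)

_SUBCORTICAL_10 = (
    "thalamus-left", "thalamus-right",
    "striatum-left", "striatum-right",
    "hippocampus-left", "hippocampus-right",
    "amygdala-left", "amygdala-right",
    "accumbens-left", "accumbens-right",
)


def _hemi(label: str) -> str:
    if label.endswith("-left"):
        return "left"
    if label.endswith("-right"):
        return "right"
    return "midline"


def default_parcellation(kind: str) -> ParcellationConfig:
    """Return the targeted (49-node) or whole-brain (526-node) configuration."""
    if kind == "targeted":
        nodes = []
        for i in range(33):
            hemi = "left" if i % 2 == 0 else "right"
            nodes.append(
                ParcellationNode(
                    f"cortical-network-{i + 1:02d}-{hemi[0]}", "cortical-400",
                    "cortical", hemi,
                )
            )
        nodes += [
            ParcellationNode(lab, "subcortex-62", "subcortical", _hemi(lab))
            for lab in _SUBCORTICAL_10
        ]
        nodes += [
            ParcellationNode(lab, "brainstem-54", "brainstem", "midline")
            for lab in _BRAINSTEM_5
        ]
        nodes.append(
            ParcellationNode("cerebellum", "cerebellum-mdtb", "cerebellum", "none")
        )
        return ParcellationConfig("targeted", nodes).validate(49)
    if kind == "wholebrain":
        nodes = []
        for i in range(400):
            hemi = "left" if i < 200 else "right"
            nodes.append(
                ParcellationNode(
                    f"cortical-parcel-{i + 1:03d}-{hemi[0]}", "cortical-400",
                    "cortical", hemi,
                )
            )
        for i in range(62):
            hemi = "left" if i % 2 == 0 else "right"
            nodes.append(
                ParcellationNode(
                    f"subcortical-{i + 1:02d}-{hemi[0]}", "subcortex-62",
                    "subcortical", hemi,
                )
            )
        nodes += [
            ParcellationNode(f"brainstem-{i + 1:02d}", "brainstem-54", "brainstem", "midline")
            for i in range(54)
        ]
        nodes += [
            ParcellationNode(f"cerebellum-parcel-{i + 1:02d}", "cerebellum-mdtb",
                             "cerebellum", "none")
            for i in range(10)
        ]
        return ParcellationConfig("wholebrain", nodes).validate(526)
    raise ValueError(f"unknown parcellation kind {kind!r} (targeted|wholebrain)")
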