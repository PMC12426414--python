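"""Electrode montage: ordered channel labels and named channel clusters.

The default montage is the 59-channel 10-10 ring-electrode layout used for
simultaneous resting and TMS-locked EEG, with the canonical M1 clusters
(nine electrodes surrounding C3 / C4) and a frontal cluster used for the
frontal delta features.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: 59-label 10-10 layout (frontal to occipital, left to right).
DEFAULT_59 = (
    "Fp1", "Fpz", "Fp2",
    "AF3", "AFz", "AF4",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)

M1_LEFT = ("FC5", "FC3", "FC1", "C5", "C3", "C1", "CP5", "CP3", "CP1")
M1_RIGHT = ("FC6", "FC4", "FC2", "C6", "C4", "C2", "CP6", "CP4", "CP2")
FRONTAL = ("Fp1", "Fp2", "F7", "F3", "Fz", "F2", "F4", "F8")


def _default_clusters() -> dict[str, tuple[str, ...]]:
    return {"m1_left": M1_LEFT, "m1_right": M1_RIGHT, "frontal": FRONTAL}


@dataclass(frozen=True)
class Montage:
    """Ordered channel labels plus named clusters.

    Parameters
    ----------
    names
        Ordered, unique channel labels.
    clusters
        Mapping of cluster name to a tuple of labels; every label must be
        present in ``names``.
    """

    names: tuple[str, ...] = DEFAULT_59
    clusters: dict[str, tuple[str, ...]] = field(default_factory=_default_clusters)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            dupes = {n for n in self.names if list(self.names).count(n) > 1}
            raise ValueError(f"duplicate channel labels: {sorted(dupes)}")
        known = set(self.names)
        for cname, labels in self.clusters.items():
            missing = [lab for lab in labels if lab not in known]
            if missing:
                raise ValueError(
                    f"cluster {cname!r} references unknown channels {missing}"
                )

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, label: str) -> int:
        """Row index of a channel label; raises ``KeyError`` if unknown."""
        try:
            return self.names.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def cluster_indices(self, cluster: str) -> list[int]:
        if cluster not in self.clusters:
            raise KeyError(f"cluster {cluster!r} not defined in montage")
        labels = self.clusters[cluster]
        if not labels:
            raise ValueError(f"cluster {cluster!r} is empty")
        return [self.index(lab) for lab in labels]
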