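"""Run configuration shared by the scoring and fusion steps."""

from __future__ import annotations

from dataclasses import asdict, dataclass

from .graph_metrics import METRICS


@dataclass
class FusionConfig:
    """Knobs for candidate scoring and network fusion.

    metric:
        Graph property compared across conditions: ``degree`` (default, the
        conventional choice for state discrimination), ``clustering`` or
        ``efficiency``.
    fdr_q:
        Benjamini–Hochberg edge FDR level used when thresholding each
        connectivity slice into a binary graph.
    edge_sign:
        ``positive`` keeps only positive-correlation significant edges;
        ``absolute`` keeps both signs.
    paired:
        With two conditions, use a paired t-test (the same subjects perform
        both conditions in a within-subject design); set False for the
        independent-samples test.
    """

    metric: str = "degree"
    fdr_q: float = 0.05
    edge_sign: str = "positive"
    paired: bool = True

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(
                f"metric must be one of {METRICS}, got {self.metric!r}"
            )
        if not 0 < self.fdr_q < 1:
            raise ValueError(f"fdr_q must be in (0, 1), got {self.fdr_q}")
        if self.edge_sign not in ("positive", "absolute"):
            raise ValueError(
                f"edge_sign must be 'positive' or 'absolute', "
                f"got {self.edge_sign!r}"
            )

    def to_dict(self) -> dict:
        return asdict(self)
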