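"""The phantom validation study: cohort generation through repeated training.

Since the clinical cohort is not public, the pipeline is validated
end-to-end on a synthetic cohort with well-separated class templates:
generate class-conditioned phantoms, extract sliding-window vascular
graphs, and run the repeated stratified split/train/test protocol.  The
study answers whether the full chain — RF simulation, segmentation,
feature extraction, graph construction, classification, majority voting —
recovers the known class structure.

Default problem sizes: 8 specimens per class, 45 B-scans per C-scan
(5 windows of 41 at stride 1), 5 protocol repeats at 60 epochs with the
learning-rate decay milestones scaled proportionally into the shorter
schedule.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

from .graph_builder import build_cscan_graphs
from .inference import sliding_window_graphs
from .model import VGNConfig, run_protocol
from .phantom import generate_cohort, generate_phantom
from .types import CScan, VascularGraph

STUDY_N_PER_CLASS = 8
STUDY_N_BSCANS = 45
STUDY_N_REPEATS = 5
STUDY_EPOCHS = 60
STUDY_MILESTONES = (30, 45)


def build_cohort_graphs(
    n_per_class: int = STUDY_N_PER_CLASS,
    seed: int = 0,
    n_bscans: int = STUDY_N_BSCANS,
    window: int = 41,
) -> Tuple[List[VascularGraph], Dict[str, int]]:
    """Generate a labeled phantom cohort and its sliding-window graphs."""
    specs, manifest = generate_cohort(n_per_class=n_per_class, seed=seed,
                                      n_bscans=n_bscans)
    graphs: List[VascularGraph] = []
    for sid, spec in zip(manifest, specs):
        bscans, _ = generate_phantom(spec)
        cscan = CScan(bscans=bscans, specimen_id=sid, label=manifest[sid])
        bscan_graphs = build_cscan_graphs(cscan)
        graphs.extend(sliding_window_graphs(cscan, window=window,
                                            bscan_graphs=bscan_graphs))
    return graphs, manifest


def run_study(
    seed: int = 0,
    n_per_class: int = STUDY_N_PER_CLASS,
    n_repeats: int = STUDY_N_REPEATS,
    epochs: int = STUDY_EPOCHS,
    n_bscans: int = STUDY_N_BSCANS,
    config: Optional[VGNConfig] = None,
    graphs: Optional[List[VascularGraph]] = None,
    manifest: Optional[Dict[str, int]] = None,
) -> Dict[str, object]:
    """Run the full phantom study and return aggregated metrics.

    Everything is derived from ``seed``: the cohort, the splits, and the
    network initializations.  Pass precomputed ``graphs``/``manifest`` to
    reuse a cohort.
    """
    if graphs is None or manifest is None:
        graphs, manifest = build_cohort_graphs(n_per_class=n_per_class, seed=seed,
                                               n_bscans=n_bscans)
    if config is None:
        milestones = tuple(int(round(epochs * m / 200)) for m in (100, 150))
        config = VGNConfig(epochs=epochs, milestones=milestones, batch_size=16,
                           seed=seed)
    results = run_protocol(graphs, manifest, n_repeats=n_repeats, config=config,
                           seed=seed + 1)
    results["n_graphs"] = len(graphs)
    results["n_specimens"] = len(manifest)
    return results
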