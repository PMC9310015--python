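"""Plotting helpers for reconstructed skeletons."""

from __future__ import annotations

from typing import Optional, Sequence

from .directed_search import Skeleton
from .geometry import BBox


def plot_skeleton(
    skel: Skeleton,
    ax=None,
    detections: Optional[Sequence[BBox]] = None,
    invert_y: bool = True,
):
    """Draw the main stem, branches and discarded nodes on a matplotlib axis.

    Image coordinates are used directly, with the y axis inverted so the
    plant grows upward on screen.
    """
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 8))
    xs = [p.x for p in skel.main_stem]
    ys = [p.y for p in skel.main_stem]
    ax.plot(xs, ys, "o-", color="forestgreen", lw=2, label="main stem")
    for i, b in enumerate(skel.branches):
        attach = skel.main_stem[b.attach_index]
        bx = [attach.x] + [p.x for p in b.chain]
        by = [attach.y] + [p.y for p in b.chain]
        ax.plot(bx, by, "s-", color="darkorange", lw=1.5,
                label="branch" if i == 0 else None)
    if skel.discarded:
        ax.plot(
            [p.x for p in skel.discarded],
            [p.y for p in skel.discarded],
            "x", color="crimson", label="discarded",
        )
    if detections:
        for d in detections:
            ax.add_patch(
                Rectangle(
                    (d.left, d.top), d.width, d.height,
                    fill=False, ec="steelblue", lw=0.6,
                )
            )
    if invert_y and not ax.yaxis_inverted():
        ax.invert_yaxis()
    ax.set_xlabel("column (px)")
    ax.set_ylabel("row (px)")
    ax.legend(loc="best", fontsize=8)
    ax.set_aspect("equal")
    return ax
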