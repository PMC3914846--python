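"""Windowed percent-identity profile of an alignment, and its heatmap.

For each non-gap query column ``Q'_i`` (1-based alignment index *i*),
the local identity is the average of the match sequence M over a window
of size *w* centred on *i*, with ``z = floor(w/2)``:

    f(Q'_i) = 1/(z + m - i + 1) * sum_{j=-z}^{m-i} M_{i+j}   if i + z > m
    f(Q'_i) = 1/(z + i)         * sum_{j=1-i}^{z}  M_{i+j}   if i - z <= 0
    f(Q'_i) = 1/(2z + 1)        * sum_{j=-z}^{z}   M_{i+j}   otherwise

The two boundary branches are exactly the central average with the
window clipped to ``[1, m]`` and the normaliser reduced to the clipped
count; should *w* span more than the whole alignment, the window is
clipped on both sides the same way. Window sums run over alignment
columns, so gap columns depress identity through M = 0 — indels show up
as low-identity stretches, which is the point of the heatmap.

Collecting f(Q'_i) for the non-gap query columns, in query order, gives
the profile vector P of length q (the ungapped query length). Each P_i
is mapped through a colour gradient on a fixed 0–100% scale to render
one heatmap cell per query nucleotide, with ORF bars drawn above.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .align import AlignmentResult
from .errors import ParameterError
from .model import OrfInterval

__all__ = [
    "IdentityProfile",
    "compute_profile",
    "reference_profile",
    "profile_to_rgb",
    "render_heatmap",
    "write_profile_tsv",
]

DEFAULT_WINDOW = 21
DEFAULT_GRADIENT = "viridis"


@dataclass
class IdentityProfile:
    """Windowed identity P (one value in [0, 1] per query nucleotide).

    ``columns[k]`` is the 0-based alignment column holding query
    nucleotide *k*; ``label`` names the sequence the profile tracks.
    """

    values: np.ndarray
    window: int
    columns: np.ndarray
    label: str = "query"

    @property
    def half_window(self) -> int:
        return self.window // 2

    @property
    def q(self) -> int:
        return len(self.values)

    @property
    def query_positions(self) -> np.ndarray:
        """P index -> 0-based position in the ungapped query (identity map)."""
        return np.arange(self.q)


def _windowed_identity(match_seq: np.ndarray, w: int) -> np.ndarray:
    """f evaluated at every alignment column (1-based i = 1..m)."""
    m = len(match_seq)
    z = w // 2
    csum = np.concatenate([[0], np.cumsum(match_seq, dtype=np.float64)])
    i = np.arange(1, m + 1)
    out = np.empty(m, dtype=np.float64)
    upper = i + z > m
    lower = i - z <= 0
    mid = ~(upper | lower)
    # interior: window [i-z, i+z], count 2z+1
    out[mid] = (csum[i[mid] + z] - csum[i[mid] - z - 1]) / (2 * z + 1)
    # right edge: window [i-z, m], count z + m - i + 1
    only_up = upper & ~lower
    out[only_up] = (csum[m] - csum[i[only_up] - z - 1]) / (z + m - i[only_up] + 1)
    # left edge: window [1, i+z], count z + i
    only_lo = lower & ~upper
    out[only_lo] = (csum[i[only_lo] + z] - csum[0]) / (z + i[only_lo])
    # both (w spans the whole alignment): clip to [1, m]
    both = upper & lower
    if both.any():
        out[both] = csum[m] / m
    return out


def compute_profile(a: AlignmentResult, w: int = DEFAULT_WINDOW, *, label: str = "query") -> IdentityProfile:
    """Compute the identity profile P of the query from an alignment.

    ``w`` must be odd and positive, and at most ``2m - 1`` so that the
    window never overruns both alignment ends at once.
    """
    if w < 1 or w % 2 == 0:
        raise ParameterError(f"window must be a positive odd integer, got {w}")
    m = a.m
    if w > 2 * m - 1:
        raise ParameterError(f"window {w} exceeds 2*m-1 = {2 * m - 1}")
    f_all = _windowed_identity(np.asarray(a.match_seq), w)
    q_arr = np.frombuffer(a.q_aligned.encode(), dtype="S1")
    columns = np.flatnonzero(q_arr != b"-")
    return IdentityProfile(
        values=f_all[columns], window=w, columns=columns, label=label
    )


def reference_profile(a: AlignmentResult, w: int = DEFAULT_WINDOW, *, label: str = "reference") -> IdentityProfile:
    """The reciprocal profile: the reference viewed as the query."""
    return compute_profile(a.swapped(), w, label=label)


def profile_to_rgb(values: np.ndarray, gradient: str = DEFAULT_GRADIENT) -> np.ndarray:
    """Map profile values through a colour map on a fixed 0..1 scale.

    Returns a (q, 3) float array of RGB in [0, 1]; this is exactly the
    colour strip the heatmap renderer draws, exposed so tests can assert
    on rendered cell colours.
    """
    import matplotlib

    cmap = matplotlib.colormaps[gradient]
    return cmap(np.clip(np.asarray(values, dtype=float), 0.0, 1.0))[:, :3]


def render_heatmap(
    profiles: Sequence[IdentityProfile],
    features: Sequence[Sequence[tuple[str, OrfInterval]]] | None = None,
    gradient: str = DEFAULT_GRADIENT,
    out: str | Path = "heatmap.png",
    title: str | None = None,
) -> Path:
    """Render one colour strip per profile with ORF bars drawn above.

    ``features[k]`` lists ``(label, interval)`` ORF annotations for
    profile *k* in that profile's own (query) coordinates; mORF bars are
    drawn solid, uORF bars above them. When two profiles are given the
    reciprocal strip is drawn below the query strip. A 0–100% scale bar
    is always included.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.cm import ScalarMappable
    from matplotlib.colors import Normalize

    if not profiles:
        raise ParameterError("render_heatmap needs at least one profile")
    if features is None:
        features = [[] for _ in profiles]
    if len(features) != len(profiles):
        raise ParameterError("one feature list per profile required")

    n = len(profiles)
    fig, axes = plt.subplots(
        n, 1, figsize=(10, 1.8 * n + 0.8), squeeze=False,
        constrained_layout=True,
    )
    for ax, prof, feats in zip(axes[:, 0], profiles, features):
        rgb = profile_to_rgb(prof.values, gradient)
        ax.imshow(
            rgb[np.newaxis, :, :],
            aspect="auto",
            interpolation="nearest",
            extent=(0.5, prof.q + 0.5, 0.0, 1.0),
        )
        # lane-stack the ORF bars: overlapping intervals move up a lane
        lanes: list[int] = []  # rightmost end per lane
        for name, iv in sorted(feats, key=lambda x: (x[1].start, -len(x[1]))):
            lane = next((k for k, e in enumerate(lanes) if iv.start >= e), None)
            if lane is None:
                lane = len(lanes)
                lanes.append(iv.end)
            else:
                lanes[lane] = iv.end
            level = 1.15 + 0.4 * lane
            ax.plot(
                [iv.start + 1, iv.end],
                [level, level],
                lw=4,
                solid_capstyle="butt",
                color="black" if name.lower().startswith("m") else "dimgray",
                clip_on=False,
            )
            ax.annotate(
                name,
                ((iv.start + 1 + iv.end) / 2, level + 0.08),
                ha="center",
                va="bottom",
                fontsize=7,
                annotation_clip=False,
            )
        ax.set_xlim(0.5, prof.q + 0.5)
        ax.set_ylim(0, 1)
        ax.set_yticks([])
        ax.set_ylabel(prof.label, rotation=0, ha="right", va="center", fontsize=9)
    axes[-1, 0].set_xlabel("position (nt, 1-based)")
    sm = ScalarMappable(norm=Normalize(0, 100), cmap=gradient)
    fig.colorbar(sm, ax=axes[:, 0], label="% identity", fraction=0.08)
    if title:
        fig.suptitle(title, fontsize=10)
    out = Path(out)
    try:
        fig.savefig(out, dpi=150)
    finally:
        plt.close(fig)
    return out


def write_profile_tsv(profile: IdentityProfile, path: str | Path) -> None:
    """Dump P as TSV: 1-based position, identity in [0, 1]."""
    with open(path, "w") as fh:
        fh.write("position\tidentity\n")
        for k, v in enumerate(profile.values, start=1):
            fh.write(f"{k}\t{v:.6f}\n")
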