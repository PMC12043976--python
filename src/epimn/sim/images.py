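"""Synthetic neurite fields with controllable fragmentation.

Each neurite is a smooth random path rendered as a tube of half-width 2-4 px,
optionally branching, confined to its own horizontal band of the image so
that structures from different neurites never merge into one connected
component. The fragmentation parameter f in [0, 1] converts a fraction f of
each path's segments into strings of compact elliptical blebs (area within
the fragment-detector's size window, circularity >= 0.3, gaps >= 3 px), so
f = 0 yields only continuous low-circularity tubes (degeneration index 0)
and f = 1 yields only qualifying fragments (degeneration index 1).
Fragmented segments are a prefix of a seeded random permutation, making the
fragment set - and hence the DI - monotone in f for paired seeds.

Channels: neurite intensity, synaptic puncta (small disks along the tubes),
and nuclei (soma disks). Ground truth records the tube, fragment, soma, and
puncta pixel sets plus the branch and puncta counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import draw

from ..morphometry import IntensityImage
from ._rng import substream

__all__ = ["ImageTruth", "simulate_neurite_image"]


@dataclass
class ImageTruth:
    fragmentation: float
    n_neurites: int
    branch_count: int
    puncta_count: int
    tube_mask: np.ndarray       # intact tube pixels
    fragment_mask: np.ndarray   # bleb pixels
    soma_mask: np.ndarray
    puncta_mask: np.ndarray

    @property
    def neurite_mask(self) -> np.ndarray:
        """Foreground a segmentation of the neurite channel should recover."""
        return self.tube_mask | self.fragment_mask


def _smooth_path(
    rng: np.random.Generator,
    y0: float,
    x0: float,
    y_band: tuple[float, float],
    shape: tuple[int, int],
    n_steps: int = 60,
    step: float = 8.0,
) -> np.ndarray:
    """Random path with momentum (low curvature), clipped to its band."""
    pts = [(y0, x0)]
    heading = rng.uniform(-0.3, 0.3)
    direction = 1.0 if x0 < shape[1] / 2 else -1.0
    y, x = y0, x0
    for _ in range(n_steps):
        heading += rng.normal(0.0, 0.18)
        heading = float(np.clip(heading, -0.9, 0.9))
        x += direction * step * np.cos(heading)
        y += step * np.sin(heading)
        y = float(np.clip(y, y_band[0], y_band[1]))
        if not (2 <= x < shape[1] - 3):
            break
        pts.append((y, x))
    return np.asarray(pts)


def _stamp_tube(mask: np.ndarray, path: np.ndarray, half_width: int) -> None:
    for (y1, x1), (y2, x2) in zip(path[:-1], path[1:]):
        rr, cc = draw.line(int(y1), int(x1), int(y2), int(x2))
        for r, c in zip(rr, cc):
            dr, dc = draw.disk((r, c), half_width, shape=mask.shape)
            mask[dr, dc] = True


def _stamp_blebs(
    mask: np.ndarray,
    path: np.ndarray,
    seg_ids: list[int],
    params: np.ndarray,
) -> int:
    """Elliptical blebs along a fragmented run with >= 3 px gaps.

    ``params`` holds one pre-drawn (r_major, axis_ratio, rotation) row per
    path segment, so the same segment always produces the same bleb no
    matter which fragmentation level selected it.
    """
    n = 0
    spacing = 1e9  # allow a bleb at the start of each run
    for s in seg_ids:
        y1, x1 = path[s]
        y2, x2 = path[s + 1]
        spacing += float(np.hypot(y2 - y1, x2 - x1))
        r_major, ratio, rotation = params[s]
        if spacing < 2 * r_major + 4:
            continue
        spacing = 0.0
        rr, cc = draw.ellipse(
            int((y1 + y2) / 2), int((x1 + x2) / 2),
            float(r_major), float(r_major * ratio),
            shape=mask.shape,
            rotation=float(rotation),
        )
        mask[rr, cc] = True
        n += 1
    return n


def simulate_neurite_image(
    width: int = 1024,
    height: int = 1024,
    n_neurites: int = 6,
    branch_prob: float = 0.3,
    f: float = 0.0,
    soma_count: int = 0,
    puncta_rate: float = 2.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[dict[str, IntensityImage], ImageTruth]:
    """Render a synthetic neurite field and its ground truth.

    ``f`` is the fragmentation fraction; ``puncta_rate`` is puncta per 100 px
    of path length; ``soma_count`` soma disks (radius >= 12 px) sit at path
    origins. Returns channels {"neurite", "puncta", "nucleus"} plus the
    truth masks.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"fragmentation f={f} outside [0,1]")
    shape = (height, width)
    rng_path = substream(seed, "image/paths")
    rng_frag = substream(seed, "image/fragments")
    rng_punc = substream(seed, "image/puncta")
    rng_noise = substream(seed, "image/noise")

    tube = np.zeros(shape, dtype=bool)
    frag = np.zeros(shape, dtype=bool)
    soma = np.zeros(shape, dtype=bool)
    puncta = np.zeros(shape, dtype=bool)

    band_h = height / n_neurites
    margin = 14
    branch_count = 0
    puncta_count = 0
    all_paths: list[np.ndarray] = []

    for i in range(n_neurites):
        band = (i * band_h + margin, (i + 1) * band_h - margin)
        if band[1] <= band[0]:
            raise ValueError("image too small for this many neurites")
        y0 = float(rng_path.uniform(*band))
        x0 = 4.0 if i % 2 == 0 else width - 5.0
        half_width = int(rng_path.integers(2, 5))
        main = _smooth_path(rng_path, y0, x0, band, shape)
        paths = [(main, half_width)]
        if len(main) > 10 and rng_path.random() < branch_prob:
            k = int(rng_path.integers(4, len(main) - 4))
            by, bx = main[k]
            branch = _smooth_path(rng_path, by, bx, band, shape,
                                  n_steps=len(main) - k)
            if len(branch) > 3:
                paths.append((branch, half_width))
                branch_count += 1

        for path, hw in paths:
            all_paths.append(path)
            # Split the path into segments; fragment a seeded-permutation
            # prefix of them so the fragmented set grows monotonically in f.
            # Both the permutation and the per-segment bleb geometry are
            # drawn up front with a fixed draw count, so they are identical
            # across fragmentation levels for the same seed.
            n_seg = len(path) - 1
            order = rng_frag.permutation(n_seg)
            params = np.column_stack(
                [
                    rng_frag.uniform(3.5, 6.0, size=n_seg),
                    rng_frag.uniform(0.65, 1.0, size=n_seg),
                    rng_frag.uniform(0.0, np.pi, size=n_seg),
                ]
            )
            n_fragged = int(round(f * n_seg))
            fragged = set(order[:n_fragged].tolist())
            intact_runs: list[list[int]] = [[]]
            frag_runs: list[list[int]] = [[]]
            for s in range(n_seg):
                if s in fragged:
                    frag_runs[-1].append(s)
                    if intact_runs[-1]:
                        intact_runs.append([])
                else:
                    intact_runs[-1].append(s)
                    if frag_runs[-1]:
                        frag_runs.append([])
            for run in intact_runs:
                if run:
                    seg_path = path[run[0] : run[-1] + 2]
                    _stamp_tube(tube, seg_path, hw)
            for run in frag_runs:
                if run:
                    _stamp_blebs(frag, path, run, params)

    # Keep components clean: a bleb that lands within 3 px of an intact tube
    # would merge with it, so such blebs are dropped whole. The fragment mask
    # then contains only isolated, qualifying particles.
    if tube.any() and frag.any():
        from scipy import ndimage as ndi

        near_tube = ndi.binary_dilation(tube, iterations=3)
        labels, n_lab = ndi.label(frag, structure=np.ones((3, 3)))
        touching = np.unique(labels[near_tube & (labels > 0)])
        if touching.size:
            frag &= ~np.isin(labels, touching)

    # Enforce the generator's contract that every fragment is a qualifying
    # particle: blebs from crossing runs (e.g. a branch origin) can merge
    # into an oversized or low-circularity blob, which is pruned whole.
    if frag.any():
        from skimage import measure

        from ..morphometry import DI_CIRCULARITY_RANGE, DI_SIZE_RANGE, _particles

        bad = [
            p.label
            for p in _particles(frag)
            if not (
                DI_SIZE_RANGE[0] <= p.area_px <= DI_SIZE_RANGE[1]
                and DI_CIRCULARITY_RANGE[0] <= p.circularity <= DI_CIRCULARITY_RANGE[1]
            )
        ]
        if bad:
            lab = measure.label(frag, connectivity=2)
            frag &= ~np.isin(lab, bad)

    for i in range(soma_count):
        band = (i % n_neurites) * band_h
        cy = float(np.clip(band + band_h / 2, 16, height - 17))
        cx = float(rng_path.uniform(30, width - 31))
        rr, cc = draw.disk((cy, cx), float(rng_path.uniform(12, 18)), shape=shape)
        soma[rr, cc] = True

    # Puncta along the tubes.
    for path in all_paths:
        seg_lens = np.hypot(*(np.diff(path, axis=0).T))
        total_len = float(seg_lens.sum())
        n_p = rng_punc.poisson(puncta_rate * total_len / 100.0)
        for _ in range(n_p):
            k = int(rng_punc.integers(0, len(path)))
            y, x = path[k]
            rr, cc = draw.disk(
                (float(y + rng_punc.normal(0, 1.5)), float(x + rng_punc.normal(0, 1.5))),
                float(rng_punc.uniform(1.2, 3.5)),
                shape=shape,
            )
            puncta[rr, cc] = True
            puncta_count += 1

    def _render(mask_sets: list[tuple[np.ndarray, float]]) -> IntensityImage:
        img = np.zeros(shape, dtype=float)
        for m, level in mask_sets:
            img[m] = np.maximum(img[m], level)
        if noise_sd > 0:
            img = np.clip(img + rng_noise.normal(0.0, noise_sd, size=shape), 0, None)
        return IntensityImage(img)

    channels = {
        "neurite": _render([(tube, 0.85), (frag, 0.85), (soma, 1.0)]),
        "puncta": _render([(puncta, 0.9)]),
        "nucleus": _render([(soma, 0.95)]),
    }
    truth = ImageTruth(
        fragmentation=f,
        n_neurites=n_neurites,
        branch_count=branch_count,
        puncta_count=puncta_count,
        tube_mask=tube,
        fragment_mask=frag,
        soma_mask=soma,
        puncta_mask=puncta,
    )
    return channels, truth
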