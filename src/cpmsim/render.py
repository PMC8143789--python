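"""Deterministic PNG rendering of lattice and CA states."""

from __future__ import annotations

import numpy as np
from PIL import Image

from .ca import CAState
from .errors import ConfigurationError
from .lattice import LatticeState, shift_grid

BACKGROUND_COLOR = (0, 0, 0)
# fixed default cycle so regression images are comparable across runs
DEFAULT_KIND_COLORS = (
    (160, 160, 160),
    (0, 128, 255),
    (255, 96, 96),
    (64, 200, 120),
    (255, 200, 0),
    (180, 100, 255),
)

DRAW_MODES = ("kind", "cell", "border")


def default_palette(n_kinds: int) -> list[tuple[int, int, int]]:
    colors = [BACKGROUND_COLOR]
    for k in range(1, n_kinds):
        colors.append(DEFAULT_KIND_COLORS[(k - 1) % len(DEFAULT_KIND_COLORS)])
    return colors


def _border_mask(state: LatticeState) -> np.ndarray:
    mask = np.zeros(state.identity.shape, dtype=bool)
    for dx, dy in state.kernel.half:
        shifted, valid = shift_grid(state.identity, state.spec, dx, dy)
        mask |= valid & (state.identity != shifted)
    return mask & (state.identity != 0)


def render_frame(
    state: LatticeState,
    palette: list[tuple[int, int, int]] | None = None,
    draw_mode: str = "kind",
    zoom: int = 1,
) -> Image.Image:
    """Raster the grid: fill-by-kind, fill-by-cell (kind hue, per-cell shade),
    or borders-only (cheap mode for large grids)."""
    if draw_mode not in DRAW_MODES:
        raise ConfigurationError(f"unknown draw_mode {draw_mode!r}; expected one of {DRAW_MODES}")
    if palette is None:
        palette = default_palette(state.n_kinds)
    if len(palette) < state.n_kinds:
        raise ConfigurationError(
            f"palette has {len(palette)} colors but state has {state.n_kinds} kinds"
        )
    kind_grid = state.kind_arr[state.identity]
    colors = np.asarray(palette[: state.n_kinds], dtype=np.uint8)
    if draw_mode == "border":
        img = np.full((*state.identity.shape, 3), 255, dtype=np.uint8)
        img[_border_mask(state)] = (0, 0, 0)
    else:
        img = colors[kind_grid]
        if draw_mode == "cell":
            # deterministic per-cell shading + black cell borders
            shade = ((state.identity * 37) % 5) * 12
            img = np.clip(img.astype(np.int64) - shade[..., None], 0, 255).astype(np.uint8)
            img[_border_mask(state)] = (0, 0, 0)
    if zoom > 1:
        img = np.kron(img, np.ones((zoom, zoom, 1), dtype=np.uint8))
    return Image.fromarray(img, mode="RGB")


def render_ca_frame(state: CAState, zoom: int = 1) -> Image.Image:
    img = np.where(state.alive[..., None], np.uint8(0), np.uint8(255))
    img = np.repeat(img, 3, axis=2).astype(np.uint8)
    if zoom > 1:
        img = np.kron(img, np.ones((zoom, zoom, 1), dtype=np.uint8))
    return Image.fromarray(img, mode="RGB")


class FrameWriter:
    """Per-MCS hook saving a PNG every ``every`` steps (step 0 included)."""

    def __init__(self, out_dir, every: int, palette=None, draw_mode: str = "kind", zoom: int = 1):
        if every < 1:
            raise ConfigurationError("png interval must be >= 1")
        self.out_dir = out_dir
        self.every = every
        self.palette = palette
        self.draw_mode = draw_mode
        self.zoom = zoom
        self.n_written = 0

    def __call__(self, state: LatticeState, mcs: int) -> None:
        if mcs % self.every:
            return
        frame = render_frame(state, self.palette, self.draw_mode, self.zoom)
        frame.save(self.out_dir / f"frame_{mcs:06d}.png")
        self.n_written += 1
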