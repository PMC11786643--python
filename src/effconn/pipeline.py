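"""End-to-end convenience chain: recordings -> windows -> connectivity -> images."""
from __future__ import annotations

import logging

from . import classify, connectivity, imaging, io_preprocess

log = logging.getLogger(__name__)


def recordings_to_images(
    recordings,
    method: str = "DTF",
    bands: list[str] | None = None,
    config: connectivity.ConnectivityConfig | None = None,
    band_defs: dict[str, connectivity.BandDefinition] | None = None,
    image_size: int = 224,
    target_fs: float | None = None,
    window_ms: int = 5000,
    overlap: float = 0.5,
    band_edges: tuple[float, float] = (0.5, 45.0),
    drop_nonstationary: bool = False,
) -> list[imaging.ConnectivityImage]:
    """Run preprocess -> window_connectivity -> order_channels -> render for a
    list of recordings; returns one image per (window, band)."""
    band_defs = band_defs or connectivity.BANDS
    names = bands or list(band_defs)
    defs = [band_defs[b] for b in names]
    config = config or connectivity.ConnectivityConfig()
    images = []
    for rec in recordings:
        windows = io_preprocess.preprocess(
            rec, band=band_edges, target_fs=target_fs,
            window_ms=window_ms, overlap=overlap,
            drop_nonstationary=drop_nonstationary,
        )
        for win in windows:
            for cm in connectivity.window_connectivity(win, method, defs, config):
                if sorted(cm.labels) == sorted(imaging.CANONICAL_35):
                    cm = imaging.order_channels(cm)
                images.append(imaging.render_image(cm, size=image_size))
    log.info("rendered %d images (%s, bands=%s)", len(images), method, names)
    return images


def images_to_dataset(images) -> list[classify.LabeledImage]:
    return classify.as_labeled_images(images)
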