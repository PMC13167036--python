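"""Intensity-threshold toy segmenter used as a CLI plugin in tests."""

from scipy import ndimage

from filasim.predictions import PredictionSet


def segment(image, params):
    gray = image.mean(axis=2) if image.ndim == 3 else image
    fg = gray < params.get("threshold", 0.5)
    labels, _ = ndimage.label(fg)
    return PredictionSet(dialect="labels", shape=gray.shape, labels=labels)
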