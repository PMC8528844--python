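"""Two-chromogen H-DAB stain model shared by the renderer and the scorer.

IHC slides considered here carry two chromogens: hematoxylin (blue nuclear
counterstain) and DAB (brown, deposited where the Ki67 antibody binds).
In optical-density (OD) space stains mix linearly (Beer-Lambert), so an RGB
pixel is ``I = I0 * 10**(-C @ M)`` where ``C`` holds per-stain concentrations
and the rows of ``M`` are unit OD colour vectors.  Using one fixed matrix for
both synthesis and unmixing makes the colour deconvolution a well-posed
inverse problem.

The unit vectors are the standard H-DAB calibration shipped with
scikit-image (Ruifrok & Johnston); a third, orthogonal residual axis
completes the basis.
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb_from_hed

__all__ = [
    "RGB_FROM_STAINS",
    "STAINS_FROM_RGB",
    "optical_density",
    "stain_concentrations",
    "render_rgb",
    "brightness",
]

_MIN_INTENSITY = 1e-6


def _build_matrix() -> np.ndarray:
    hema = rgb_from_hed[0]
    dab = rgb_from_hed[2]
    residual = np.cross(hema, dab)
    m = np.stack([hema, dab, residual])
    return m / np.linalg.norm(m, axis=1, keepdims=True)


#: rows = (hematoxylin, DAB, residual) unit OD colour vectors
RGB_FROM_STAINS: np.ndarray = _build_matrix()
#: inverse mapping, OD -> stain concentrations
STAINS_FROM_RGB: np.ndarray = np.linalg.inv(RGB_FROM_STAINS)


def optical_density(image: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Per-channel OD of an 8-bit RGB image: ``-log10(I / I0)``."""
    scaled = np.maximum(image.astype(np.float64), _MIN_INTENSITY) / i0
    return -np.log10(np.minimum(scaled, 1.0))


def stain_concentrations(image: np.ndarray) -> np.ndarray:
    """Unmix an RGB image into (hematoxylin, DAB, residual) OD channels.

    Returns a float array of the same spatial shape with 3 stain channels.
    Negative concentrations (off-basis noise) are clipped to zero.
    """
    od = optical_density(image)
    conc = od @ STAINS_FROM_RGB
    return np.clip(conc, 0.0, None)


def render_rgb(concentrations: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Render stain concentration maps to float RGB on a background colour.

    ``background`` is the RGB triple (0-255) transmitted where no stain is
    present; stains attenuate it per Beer-Lambert.
    """
    od = concentrations @ RGB_FROM_STAINS
    bg = np.asarray(background, dtype=np.float64)
    return bg * (10.0 ** (-od))


def brightness(image: np.ndarray) -> np.ndarray:
    """Mean-RGB brightness map (0-255 scale) of an 8-bit image."""
    return image.astype(np.float64).mean(axis=-1)
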