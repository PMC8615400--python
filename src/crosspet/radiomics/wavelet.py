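"""Single-level separable 3-D wavelet decomposition into eight subbands.

Applying a low-pass (L) or high-pass (H) wavelet filter along each of the
three image axes yields eight subbands labeled LLL..HHH, the first letter
referring to axis 0 (the slowest-varying array axis).  The default
transform is the *undecimated* (stationary) wavelet transform so every
subband keeps the input shape and the tumor mask stays congruent with the
coefficients; a decimated orthogonal variant is provided for energy
bookkeeping, where Parseval's identity holds exactly.

The wavelet family defaults to Coiflet-1; any orthogonal PyWavelets name
may be substituted.
"""

from __future__ import annotations

import numpy as np
import pywt

from ..errors import ParameterError

SUBBAND_ORDER = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


def _key_to_label(key: str) -> str:
    # pywt uses 'a' (approximation, low-pass) / 'd' (detail, high-pass),
    # characters ordered by array axis
    return key.replace("a", "L").replace("d", "H")


def wavelet_decompose(
    volume: np.ndarray, wavelet: str = "coif1", *, decimated: bool = False
) -> dict[str, np.ndarray]:
    """Decompose a 3-D array into its eight single-level subbands.

    Returns a dict keyed 'LLL'..'HHH'.  Undecimated subbands have the input
    shape (odd axes are symmetrically padded to even length and cropped
    back).  The decimated variant uses periodization so that the summed
    subband energy equals the input energy for orthogonal wavelets.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ParameterError("wavelet decomposition expects a 3-D volume")
    w = pywt.Wavelet(wavelet)
    if any(n < w.dec_len for n in vol.shape):
        raise ParameterError(
            f"volume shape {vol.shape} smaller than filter support {w.dec_len}"
        )
    if decimated:
        coeffs = pywt.dwtn(vol, w, mode="periodization")
        return {_key_to_label(k): v for k, v in coeffs.items()}

    pads = [(0, n % 2) for n in vol.shape]
    padded = np.pad(vol, pads, mode="symmetric") if any(p[1] for p in pads) else vol
    coeffs = pywt.swtn(padded, w, level=1, start_level=0)[0]
    crop = tuple(slice(0, n) for n in vol.shape)
    return {_key_to_label(k): v[crop] for k, v in coeffs.items()}
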