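"""Shared label codes for tissue maps and phantom ground truth.

The same integer codes are used by the phantom's truth grid and by the
pipeline's tissue map, so predictions and ground truth compare directly.
SKULL appears only in phantom truth; a tissue map never contains it.
"""

BG = 0
SKULL = 1
CSF = 2
GM = 3
WM = 4

TISSUE_NAMES = {BG: "BG", SKULL: "SKULL", CSF: "CSF", GM: "GM", WM: "WM"}
BRAIN_TISSUES = (CSF, GM, WM)
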