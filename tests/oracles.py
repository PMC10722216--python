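"""Independent brute-force references used only by the test suite."""

import numpy as np


def guo_hall_thin(mask: np.ndarray) -> np.ndarray:
    """Guo-Hall (1989) two-subiteration thinning, implemented directly
    from the published conditions as an independent reference for skeleton
    pixel counts.  Intended for small fixtures only (pure-Python loop)."""
    img = np.asarray(mask, dtype=np.uint8).copy()
    changed = True
    while changed:
        changed = False
        for phase in (0, 1):
            padded = np.pad(img, 1)
            deletions = []
            for r, c in zip(*np.nonzero(img)):
                win = padded[r : r + 3, c : c + 3]
                p2, p3, p4 = win[0, 1], win[0, 2], win[1, 2]
                p5, p6, p7 = win[2, 2], win[2, 1], win[2, 0]
                p8, p9 = win[1, 0], win[0, 0]
                C = (
                    int(not p2 and (p3 or p4))
                    + int(not p4 and (p5 or p6))
                    + int(not p6 and (p7 or p8))
                    + int(not p8 and (p9 or p2))
                )
                N1 = int(p9 or p2) + int(p3 or p4) + int(p5 or p6) + int(p7 or p8)
                N2 = int(p2 or p3) + int(p4 or p5) + int(p6 or p7) + int(p8 or p9)
                N = min(N1, N2)
                if phase == 0:
                    m = int((p6 or p7 or not p9) and p8)
                else:
                    m = int((p2 or p3 or not p5) and p4)
                if C == 1 and 2 <= N <= 3 and m == 0:
                    deletions.append((r, c))
            for r, c in deletions:
                img[r, c] = 0
            if deletions:
                changed = True
    return img.astype(bool)


def chord_angles_on_path(path: list, half_window: int = 3) -> np.ndarray:
    """Brute-force chord orientations for an ordered simple pixel path.

    For pixel i the chord joins path[max(i-k, 0)] and path[min(i+k, n-1)];
    the angle is measured from vertical and folded into [0, 180)."""
    n = len(path)
    out = np.zeros(n)
    for i in range(n):
        r0, c0 = path[max(i - half_window, 0)]
        r1, c1 = path[min(i + half_window, n - 1)]
        out[i] = np.degrees(np.arctan2(c1 - c0, r1 - r0)) % 180.0
    return out
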