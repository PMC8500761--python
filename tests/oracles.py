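"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as the most literal possible computation
(double loops, breadth-first search, exhaustive nearest-point scans) and
deliberately shares no code with the package.
"""

from collections import deque

import numpy as np


def direct_convolve_reflect(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Double-loop 2-D convolution with reflect (symmetric) padding."""
    kh, kw = kernel.shape
    rh, rw = kh // 2, kw // 2
    padded = np.pad(img, ((rh, rh), (rw, rw)), mode="symmetric")
    h, w = img.shape
    out = np.zeros_like(img, dtype=float)
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for i in range(kh):
                for j in range(kw):
                    # convolution: kernel index runs opposite to the patch
                    acc += kernel[i, j] * padded[r + rh - (i - rh), c + rw - (j - rw)]
            out[r, c] = acc
    return out


def finite_difference_gradient(img: np.ndarray):
    """Elementwise central/one-sided differences (gy rows, gx cols)."""
    h, w = img.shape
    gy = np.zeros((h, w))
    gx = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            if 0 < r < h - 1:
                gy[r, c] = (img[r + 1, c] - img[r - 1, c]) / 2.0
            elif r == 0:
                gy[r, c] = img[1, c] - img[0, c]
            else:
                gy[r, c] = img[h - 1, c] - img[h - 2, c]
            if 0 < c < w - 1:
                gx[r, c] = (img[r, c + 1] - img[r, c - 1]) / 2.0
            elif c == 0:
                gx[r, c] = img[r, 1] - img[r, 0]
            else:
                gx[r, c] = img[r, w - 1] - img[r, w - 2]
    return gx, gy


_SECTOR_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))


def nms_double_loop(magnitude: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Directional-maximum scan: keep strictly-greater-than-both pixels.

    Same 4-sector quantization convention as the detector (the sector
    rule is a documented design choice shared by contract, not code).
    """
    h, w = magnitude.shape
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            t = direction[r, c] % np.pi
            sector = int(round(t / (np.pi / 4.0))) % 4
            dr, dc = _SECTOR_OFFSETS[sector]
            m = magnitude[r, c]
            fwd = magnitude[r + dr, c + dc] if 0 <= r + dr < h and 0 <= c + dc < w else 0.0
            bwd = magnitude[r - dr, c - dc] if 0 <= r - dr < h and 0 <= c - dc < w else 0.0
            if m > fwd and m > bwd:
                out[r, c] = m
    return out


def hysteresis_bfs(nms: np.ndarray, t_l: float, t_h: float) -> np.ndarray:
    """Flood-fill from strong pixels through weak/strong 8-neighbors."""
    h, w = nms.shape
    strong = nms >= t_h
    candidate = nms >= t_l
    edge = np.zeros((h, w), dtype=np.uint8)
    queue = deque(zip(*np.nonzero(strong)))
    for r, c in queue:
        edge[r, c] = 1
    while queue:
        r, c = queue.popleft()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and candidate[rr, cc] and not edge[rr, cc]:
                    edge[rr, cc] = 1
                    queue.append((rr, cc))
    return edge


def fom_exhaustive(detected: np.ndarray, ideal: np.ndarray, rho: float) -> float:
    """Pratt FOM via exhaustive nearest-ideal-point search."""
    det = list(zip(*np.nonzero(np.asarray(detected) > 0)))
    ide = list(zip(*np.nonzero(np.asarray(ideal) > 0)))
    if not ide:
        raise ValueError("empty ideal map")
    if not det:
        return 0.0
    total = 0.0
    for r, c in det:
        d2 = min((r - ri) ** 2 + (c - ci) ** 2 for ri, ci in ide)
        total += 1.0 / (1.0 + rho * d2)
    return total / max(len(det), len(ide))


def ssim_windowed(a: np.ndarray, b: np.ndarray, pe_max=1.0, window=8,
                  k1=0.01, k2=0.03) -> float:
    """Independent loop-based windowed SSIM (population statistics)."""
    c1 = (k1 * pe_max) ** 2
    c2 = (k2 * pe_max) ** 2
    c3 = c2 / 2.0
    h, w = a.shape
    vals = []
    for r in range(h - window + 1):
        for c in range(w - window + 1):
            wa = a[r : r + window, c : c + window].ravel()
            wb = b[r : r + window, c : c + window].ravel()
            ma, mb = wa.mean(), wb.mean()
            va = ((wa - ma) ** 2).mean()
            vb = ((wb - mb) ** 2).mean()
            cov = ((wa - ma) * (wb - mb)).mean()
            bri = (2 * ma * mb + c1) / (ma**2 + mb**2 + c1)
            con = (2 * np.sqrt(va) * np.sqrt(vb) + c2) / (va + vb + c2)
            st = (cov + c3) / (np.sqrt(va) * np.sqrt(vb) + c3)
            vals.append(bri * con * st)
    return float(np.mean(vals))


def project_feasible(alpha0: np.ndarray, y: np.ndarray, C: float,
                     iters: int = 500) -> np.ndarray:
    """Alternating projection of a point onto {0 <= a <= C, sum a*y = 0}."""
    a = alpha0.copy()
    n = len(a)
    for _ in range(iters):
        a = a - (a @ y) / n * y  # hyperplane projection (||y||^2 = n)
        a = np.clip(a, 0.0, C)
        if abs(a @ y) < 1e-12:
            break
    a = a - (a @ y) / n * y
    return np.clip(a, 0.0, C)


def kkt_residuals(model, X: np.ndarray, y: np.ndarray) -> dict:
    """KKT diagnostics of a trained dual solution.

    Returns the equality-constraint residual, the box violation, and the
    maximal violation of the optimality conditions expressed through the
    margins: y_i f(x_i) >= 1 where alpha=0, <= 1 where alpha=C, and = 1
    on unbounded support vectors.
    """
    alpha = model.alpha_
    C = model.C
    f = model.decision_function(X)
    margins = y * f
    eq = abs(float(alpha @ y))
    box = float(max(np.max(-alpha, initial=0.0), np.max(alpha - C, initial=0.0)))
    tol_a = 1e-8 * max(C, 1.0)
    lower = alpha <= tol_a
    upper = alpha >= C - tol_a
    free = ~lower & ~upper
    viol = 0.0
    if lower.any():
        viol = max(viol, float(np.max(1.0 - margins[lower], initial=0.0)))
    if upper.any():
        viol = max(viol, float(np.max(margins[upper] - 1.0, initial=0.0)))
    if free.any():
        viol = max(viol, float(np.max(np.abs(margins[free] - 1.0))))
    return {"equality": eq, "box": box, "stationarity": viol}
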