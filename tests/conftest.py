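import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_kapur(counts):
    """Independent maximum-entropy threshold oracle: evaluate the summed
    class entropies for every candidate k straight from the definition
    (0*ln 0 = 0; k valid only when both classes are nonempty) and take the
    smallest argmax."""
    counts = np.asarray(counts, dtype=float)
    p = counts / counts.sum()
    best_k, best_h = None, -np.inf
    for k in range(len(p)):
        P0 = p[: k + 1].sum()
        P1 = p[k + 1:].sum()
        if P0 <= 0 or P1 <= 0:
            continue
        h = 0.0
        for q, P in ((p[: k + 1], P0), (p[k + 1:], P1)):
            q = q[q > 0] / P
            h -= np.sum(q * np.log(q))
        if h > best_h + 1e-12:
            best_h, best_k = h, k
    return best_k


def naive_dilate(img, se):
    """Double-loop max-filter dilation oracle with background padding."""
    img = np.asarray(img)
    k = se.shape[0] // 2
    h, w = img.shape
    out = np.zeros_like(img)
    for i in range(h):
        for j in range(w):
            best = 0
            for di in range(-k, k + 1):
                for dj in range(-k, k + 1):
                    if not se[di + k, dj + k]:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < h and 0 <= jj < w and img[ii, jj]:
                        best = 1
                        break
                if best:
                    break
            out[i, j] = best
    return out


def flood_fill_labels(img, connectivity=8):
    """Stack-based connected-component labeling oracle; returns the label
    partition as a frozenset of frozensets of pixel coordinates."""
    img = np.asarray(img) != 0
    h, w = img.shape
    seen = np.zeros((h, w), dtype=bool)
    if connectivity == 8:
        nbrs = [(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1) if (a, b) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    comps = []
    for i in range(h):
        for j in range(w):
            if not img[i, j] or seen[i, j]:
                continue
            stack, comp = [(i, j)], set()
            seen[i, j] = True
            while stack:
                a, b = stack.pop()
                comp.add((a, b))
                for da, db in nbrs:
                    x, y = a + da, b + db
                    if 0 <= x < h and 0 <= y < w and img[x, y] and not seen[x, y]:
                        seen[x, y] = True
                        stack.append((x, y))
            comps.append(frozenset(comp))
    return frozenset(comps)


def center_error(result, truth):
    """Euclidean distance from a detection target to the scene ground truth,
    infinite when recognition failed."""
    if result is None or not result.success:
        return np.inf
    return float(np.hypot(result.target[0] - truth.center_true[0],
                          result.target[1] - truth.center_true[1]))
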