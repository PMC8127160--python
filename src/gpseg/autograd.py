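"""Minimal reverse-mode automatic differentiation on numpy arrays.

This backend provides exactly the operations the segmentation network and its
composite loss need: FFT-accelerated 3D convolution with dilation, deformable
(trilinearly sampled) convolution, batch normalisation, 2x max/average pooling,
factor-2 trilinear upsampling, channel concatenation, softmax and the usual
elementwise algebra.  Tensors carry a ``data`` array and, after ``backward()``,
a ``grad`` array of the same shape and dtype.

Arrays keep whatever float dtype they are given (float32 for training speed,
float64 when exactness matters in verification code).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided
from scipy import fft as _fft

__all__ = ["Tensor", "concat", "conv3d", "deformable_conv3d_op", "maxpool2",
           "avgpool2", "upsample2", "batchnorm", "softmax_channels"]


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.data = arr
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents = ()

    # -- graph plumbing -----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(g, self.data.shape),
                                 dtype=self.data.dtype)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise algebra ------------------------------------------------

    def __add__(self, other):
        return _binary(self, other, np.add,
                       lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract,
                       lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return _as_tensor(other, self.dtype) - self

    def __mul__(self, other):
        return _binary(self, other, np.multiply,
                       lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(self, other, np.divide,
                       lambda g, a, b: g / b, lambda g, a, b: -g * a / (b * b))

    def __rtruediv__(self, other):
        return _as_tensor(other, self.dtype) / self

    def __neg__(self):
        return self * -1.0

    def __pow__(self, exponent: float):
        x = self
        out = _result(np.power(x.data, exponent), (x,))
        if out.requires_grad:
            def bw(g):
                if x.requires_grad:
                    x._accumulate(g * exponent * np.power(x.data, exponent - 1))
            out._backward = bw
        return out

    def sum(self):
        x = self
        out = _result(np.asarray(x.data.sum(), dtype=x.dtype), (x,))
        if out.requires_grad:
            def bw(g):
                if x.requires_grad:
                    x._accumulate(np.broadcast_to(g, x.shape).astype(x.dtype))
            out._backward = bw
        return out

    def mean(self):
        return self.sum() / float(self.data.size)

    def relu(self):
        x = self
        out = _result(np.maximum(x.data, 0), (x,))
        if out.requires_grad:
            mask = x.data > 0
            def bw(g):
                if x.requires_grad:
                    x._accumulate(g * mask)
            out._backward = bw
        return out

    def sigmoid(self):
        x = self
        with np.errstate(over="ignore"):
            s = 1.0 / (1.0 + np.exp(-x.data))
        out = _result(s.astype(x.dtype), (x,))
        if out.requires_grad:
            def bw(g):
                if x.requires_grad:
                    x._accumulate(g * s * (1.0 - s))
            out._backward = bw
        return out

    def __getitem__(self, key):
        x = self
        out = _result(x.data[key], (x,))
        if out.requires_grad:
            def bw(g):
                if x.requires_grad:
                    full = np.zeros_like(x.data)
                    full[key] = g
                    x._accumulate(full)
            out._backward = bw
        return out


def _as_tensor(value, dtype):
    if isinstance(value, Tensor):
        return value
    t = Tensor(np.asarray(value, dtype=dtype))
    return t


def _result(data, parents):
    out = Tensor(data)
    live = tuple(p for p in parents if p.requires_grad)
    out.requires_grad = bool(live)
    out._parents = live
    return out


def _binary(a, b, fwd, bw_a, bw_b):
    b = _as_tensor(b, a.dtype)
    out = _result(fwd(a.data, b.data), (a, b))
    if out.requires_grad:
        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(bw_a(g, a.data, b.data), a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(bw_b(g, a.data, b.data), b.shape))
        out._backward = bw
    return out


def _unbroadcast(grad, shape):
    """Sum a broadcast gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def concat(tensors, axis=0):
    datas = [t.data for t in tensors]
    out = _result(np.concatenate(datas, axis=axis), tuple(tensors))
    if out.requires_grad:
        sizes = [d.shape[axis] for d in datas]
        splits = np.cumsum(sizes)[:-1]
        def bw(g):
            parts = np.split(g, splits, axis=axis)
            for t, p in zip(tensors, parts):
                if t.requires_grad:
                    t._accumulate(p)
        out._backward = bw
    return out


# ---------------------------------------------------------------------------
# 3D convolution (channels-first: x (Cin, D, H, W), w (Cout, Cin, k, k, k))
# ---------------------------------------------------------------------------

# switch to the FFT path when the im2col patch matrix would exceed this many
# bytes; below it a single GEMM is both exact and faster than many small FFTs
_IM2COL_MAX_BYTES = 64e6


def _dilate_kernel(w, dilation):
    if dilation == 1:
        return w
    k = w.shape[-1]
    ke = dilation * (k - 1) + 1
    out = np.zeros(w.shape[:-3] + (ke, ke, ke), dtype=w.dtype)
    out[..., ::dilation, ::dilation, ::dilation] = w
    return out


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           padding: int = 0, dilation: int = 1) -> Tensor:
    """Size-general cross-correlation; output axis length = n + 2p - de + 1
    with de = dilation*(k-1) + 1."""
    cin, D, H, W = x.data.shape
    cout, cin2, k = w.data.shape[0], w.data.shape[1], w.data.shape[2]
    if cin2 != cin:
        raise ValueError(f"conv3d channel mismatch: input {cin}, weight {cin2}")
    ke = dilation * (k - 1) + 1
    out_shape = tuple(n + 2 * padding - ke + 1 for n in (D, H, W))
    if any(n < 1 for n in out_shape):
        raise ValueError("conv3d: kernel larger than padded input")
    cols_bytes = cin * k ** 3 * int(np.prod(out_shape)) * x.data.itemsize
    if k > 1 and cols_bytes > _IM2COL_MAX_BYTES:
        y = _conv3d_fft(x, w, padding, dilation, out_shape)
    else:
        y = _conv3d_direct(x, w, padding, dilation, out_shape)
    if b is not None:
        y = _add_channel_bias(y, b)
    return y


def _add_channel_bias(y, b):
    out = _result(y.data + b.data[:, None, None, None], (y, b))
    if out.requires_grad:
        def bw(g):
            if y.requires_grad:
                y._accumulate(g)
            if b.requires_grad:
                b._accumulate(g.sum(axis=(1, 2, 3)))
        out._backward = bw
    return out


def _conv3d_direct(x, w, padding, dilation, out_shape):
    cin = x.data.shape[0]
    cout, _, k = w.data.shape[0], w.data.shape[1], w.data.shape[2]
    p = padding
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p)))
    s = xp.strides
    view = as_strided(
        xp,
        shape=(cin, k, k, k) + out_shape,
        strides=(s[0], s[1] * dilation, s[2] * dilation, s[3] * dilation,
                 s[1], s[2], s[3]),
    )
    cols = np.ascontiguousarray(view).reshape(cin * k ** 3, -1)
    wmat = w.data.reshape(cout, cin * k ** 3)
    y = (wmat @ cols).reshape((cout,) + out_shape)
    out = _result(y, (x, w))
    if out.requires_grad:
        def bw(g):
            gmat = g.reshape(cout, -1)
            if w.requires_grad:
                w._accumulate((gmat @ cols.T).reshape(w.shape))
            if x.requires_grad:
                dcols = (wmat.T @ gmat).reshape((cin, k, k, k) + out_shape)
                dxp = np.zeros_like(xp)
                for a in range(k):
                    for bidx in range(k):
                        for c in range(k):
                            dxp[:,
                                a * dilation:a * dilation + out_shape[0],
                                bidx * dilation:bidx * dilation + out_shape[1],
                                c * dilation:c * dilation + out_shape[2],
                                ] += dcols[:, a, bidx, c]
                if p:
                    dxp = dxp[:, p:-p, p:-p, p:-p]
                x._accumulate(dxp)
        out._backward = bw
    return out


def _pad_to(arr, F):
    """Zero-extend the three trailing axes to shape F (copy)."""
    out = np.zeros(arr.shape[:-3] + tuple(F), dtype=arr.dtype)
    out[..., :arr.shape[-3], :arr.shape[-2], :arr.shape[-1]] = arr
    return out


def _rfftn_chunked(arr, F, chunk=8):
    """Batched real FFT of pre-padded data, in chunks (large batched
    transforms in one call hit a memory cliff)."""
    lead = arr.shape[:-3]
    flat = arr.reshape((-1,) + tuple(F))
    parts = [_fft.rfftn(flat[i:i + chunk], axes=(-3, -2, -1))
             for i in range(0, flat.shape[0], chunk)]
    out = np.concatenate(parts, axis=0) if len(parts) > 1 else parts[0]
    return out.reshape(lead + out.shape[-3:])


def _irfftn_chunked(spec, F, chunk=8):
    lead = spec.shape[:-3]
    flat = spec.reshape((-1,) + spec.shape[-3:])
    parts = [_fft.irfftn(flat[i:i + chunk], s=F, axes=(-3, -2, -1))
             for i in range(0, flat.shape[0], chunk)]
    out = np.concatenate(parts, axis=0) if len(parts) > 1 else parts[0]
    return out.reshape(lead + tuple(F))


def _flip_phase(F, ke, ctype):
    """Frequency-domain factors P with FFT(w) = conj(FFT(flip(w)) * P) for a
    real kernel of support ke zero-padded to F (flip within its support)."""
    fz = np.arange(F[0])[:, None, None]
    fy = np.arange(F[1])[None, :, None]
    fx = np.arange(F[2] // 2 + 1)[None, None, :]
    ang = 2.0 * np.pi * (ke - 1) * (fz / F[0] + fy / F[1] + fx / F[2])
    return np.exp(1j * ang).astype(ctype)


def _conv3d_fft(x, w, padding, dilation, out_shape):
    cin = x.data.shape[0]
    cout, _, k = w.data.shape[0], w.data.shape[1], w.data.shape[2]
    ke = dilation * (k - 1) + 1
    p = padding
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p)))
    S = xp.shape[1:]
    F = tuple(_fft.next_fast_len(int(n)) for n in S)
    wd = _dilate_kernel(w.data, dilation)
    Xf = _rfftn_chunked(_pad_to(xp, F), F)
    Wf = _rfftn_chunked(_pad_to(wd[:, :, ::-1, ::-1, ::-1], F), F)
    Yf = np.einsum("i...,oi...->o...", Xf, Wf)
    yfull = _irfftn_chunked(Yf, F)
    sl = tuple(slice(ke - 1, ke - 1 + n) for n in out_shape)
    y = np.ascontiguousarray(yfull[(slice(None),) + sl]).astype(x.dtype)
    out = _result(y, (x, w))
    if out.requires_grad:
        def bw(g):
            Gf = _rfftn_chunked(_pad_to(g, F), F)
            if x.requires_grad:
                # FFT of the unflipped kernel from the cached flipped FFT
                phase = _flip_phase(F, ke, Wf.dtype)
                dXf = np.einsum("o...,oi...->i...", Gf, np.conj(Wf * phase))
                dxp = _irfftn_chunked(dXf, F)
                dxp = dxp[:, :S[0], :S[1], :S[2]]
                if p:
                    dxp = dxp[:, p:-p, p:-p, p:-p]
                x._accumulate(dxp.astype(x.dtype))
            if w.requires_grad:
                dw = np.empty_like(w.data, dtype=np.float64)
                Gc = np.conj(Gf)
                for o in range(cout):
                    Z = Xf * Gc[o]
                    dwf = _irfftn_chunked(Z, F)
                    dw[o] = dwf[:, :ke:dilation, :ke:dilation, :ke:dilation]
                w._accumulate(dw.astype(w.dtype))
        out._backward = bw
    return out


# ---------------------------------------------------------------------------
# Deformable convolution: per-tap learned offsets, trilinear sampling
# ---------------------------------------------------------------------------

def deformable_conv3d_op(x: Tensor, offsets: Tensor, w: Tensor,
                         b: Tensor | None = None, padding: int | None = None) -> Tensor:
    """Cross-correlation whose sampling grid is displaced per tap and voxel.

    ``offsets`` has 3*k^3 channels (z, y, x displacement in voxels for each of
    the k^3 taps, tap-major).  Out-of-bounds samples read zero; sampling is
    trilinear, so gradients flow to both the input and the offsets.
    Output spatial size equals input size (size-preserving padding).
    """
    cin, D, H, W = x.data.shape
    cout, cin2, k = w.data.shape[0], w.data.shape[1], w.data.shape[2]
    if cin2 != cin:
        raise ValueError("deformable_conv3d: channel mismatch")
    nk = k ** 3
    if offsets.data.shape[0] != 3 * nk:
        raise ValueError(
            f"deformable_conv3d: expected {3 * nk} offset channels for kernel "
            f"size {k}, got {offsets.data.shape[0]}")
    if padding is None:
        padding = (k - 1) // 2
    dtype = x.dtype
    shape = (D, H, W)
    grid = np.indices(shape, dtype=dtype)                       # (3, D, H, W)
    taps = np.stack(np.meshgrid(*[np.arange(k)] * 3, indexing="ij"),
                    axis=-1).reshape(nk, 3).astype(dtype) - padding
    off = offsets.data.reshape(nk, 3, D, H, W)
    # absolute sampling position per tap/axis/voxel
    pos = grid[None] + taps[:, :, None, None, None] + off       # (nk,3,D,H,W)
    f = np.floor(pos)
    frac = pos - f
    f = f.astype(np.int64)

    dims = np.array(shape, dtype=np.int64)
    xflat = x.data.reshape(cin, -1)
    need_grad = x.requires_grad or offsets.requires_grad or w.requires_grad
    corner_vals = []       # per corner: (nk, cin, N) gathered values
    corner_idx = []        # per corner: (nk, N) flat index (clipped)
    corner_wts = []        # per corner: (nk, N) trilinear weight
    corner_valid = []
    N = D * H * W
    sampled = np.zeros((nk, cin, N), dtype=dtype)
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                cz = f[:, 0] + dz
                cy = f[:, 1] + dy
                cx = f[:, 2] + dx
                valid = ((cz >= 0) & (cz < dims[0]) & (cy >= 0) &
                         (cy < dims[1]) & (cx >= 0) & (cx < dims[2]))
                czc = np.clip(cz, 0, dims[0] - 1)
                cyc = np.clip(cy, 0, dims[1] - 1)
                cxc = np.clip(cx, 0, dims[2] - 1)
                idx = ((czc * dims[1] + cyc) * dims[2] + cxc).reshape(nk, N)
                wz = frac[:, 0] if dz else 1.0 - frac[:, 0]
                wy = frac[:, 1] if dy else 1.0 - frac[:, 1]
                wx = frac[:, 2] if dx else 1.0 - frac[:, 2]
                wt = (wz * wy * wx * valid).reshape(nk, N).astype(dtype)
                vals = np.swapaxes(xflat[:, idx], 0, 1)  # (nk, cin, N)
                sampled += vals * wt[:, None, :]
                if need_grad:
                    corner_vals.append(vals)
                    corner_idx.append(idx)
                    corner_wts.append(wt)
                    corner_valid.append(valid.reshape(nk, N))
    wmat = w.data.reshape(cout, cin, nk)
    y = np.einsum("ocr,rcn->on", wmat, sampled).reshape((cout,) + shape)
    out = _result(y, (x, offsets, w))
    if out.requires_grad:
        def bw(g):
            gflat = g.reshape(cout, N)
            dsampled = np.einsum("ocr,on->rcn", wmat, gflat)
            if w.requires_grad:
                dw = np.einsum("rcn,on->ocr", sampled, gflat)
                w._accumulate(dw.reshape(w.shape))
            if x.requires_grad:
                dx = np.zeros((cin, N), dtype=dtype)
                for idx, wt in zip(corner_idx, corner_wts):
                    contrib = dsampled * wt[:, None, :]          # (nk,cin,N)
                    flat_idx = idx.ravel()
                    for c in range(cin):
                        dx[c] += np.bincount(flat_idx,
                                             weights=contrib[:, c].ravel(),
                                             minlength=N).astype(dtype)
                x._accumulate(dx.reshape(x.shape))
            if offsets.requires_grad:
                doff = np.zeros((nk, 3, N), dtype=dtype)
                # d(weight)/d(frac) per corner, times gathered value
                corner_signs = [(dz, dy, dx)
                                for dz in (0, 1) for dy in (0, 1) for dx in (0, 1)]
                frac_f = frac.reshape(nk, 3, N)
                for (dz, dy, dx), vals, wt, valid in zip(
                        corner_signs, corner_vals, corner_wts, corner_valid):
                    inner = np.einsum("rcn,rcn->rn", dsampled, vals)
                    wz = frac_f[:, 0] if dz else 1.0 - frac_f[:, 0]
                    wy = frac_f[:, 1] if dy else 1.0 - frac_f[:, 1]
                    wx = frac_f[:, 2] if dx else 1.0 - frac_f[:, 2]
                    sz = 1.0 if dz else -1.0
                    sy = 1.0 if dy else -1.0
                    sx = 1.0 if dx else -1.0
                    v = valid
                    doff[:, 0] += inner * sz * wy * wx * v
                    doff[:, 1] += inner * wz * sy * wx * v
                    doff[:, 2] += inner * wz * wy * sx * v
                offsets._accumulate(
                    doff.reshape(offsets.shape).astype(dtype))
        out._backward = bw
    if b is not None:
        out = _add_channel_bias(out, b)
    return out


# ---------------------------------------------------------------------------
# Pooling / upsampling / normalisation
# ---------------------------------------------------------------------------

def maxpool2(x: Tensor) -> Tensor:
    c, D, H, W = x.data.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError("maxpool2 requires even spatial dimensions")
    xr = x.data.reshape(c, D // 2, 2, H // 2, 2, W // 2, 2)
    xr = np.moveaxis(xr, (2, 4, 6), (4, 5, 6)).reshape(
        c, D // 2, H // 2, W // 2, 8)
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    out = _result(np.ascontiguousarray(y), (x,))
    if out.requires_grad:
        def bw(g):
            if x.requires_grad:
                dxr = np.zeros(xr.shape, dtype=x.dtype)
                np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
                dxr = dxr.reshape(c, D // 2, H // 2, W // 2, 2, 2, 2)
                dxr = np.moveaxis(dxr, (4, 5, 6), (2, 4, 6)).reshape(c, D, H, W)
                x._accumulate(np.ascontiguousarray(dxr))
        out._backward = bw
    return out


def avgpool2(x: Tensor) -> Tensor:
    c, D, H, W = x.data.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError("avgpool2 requires even spatial dimensions")
    y = x.data.reshape(c, D // 2, 2, H // 2, 2, W // 2, 2).mean(axis=(2, 4, 6))
    out = _result(y.astype(x.dtype), (x,))
    if out.requires_grad:
        def bw(g):
            if x.requires_grad:
                gx = np.repeat(np.repeat(np.repeat(g, 2, axis=1), 2, axis=2),
                               2, axis=3) / 8.0
                x._accumulate(gx.astype(x.dtype))
        out._backward = bw
    return out


def _up1d(arr, axis):
    xm = np.moveaxis(arr, axis, -1)
    n = xm.shape[-1]
    left = np.concatenate([xm[..., :1], xm[..., :-1]], axis=-1)
    right = np.concatenate([xm[..., 1:], xm[..., -1:]], axis=-1)
    y = np.empty(xm.shape[:-1] + (2 * n,), dtype=arr.dtype)
    y[..., 0::2] = 0.75 * xm + 0.25 * left
    y[..., 1::2] = 0.75 * xm + 0.25 * right
    return np.moveaxis(y, -1, axis)


def _up1d_adjoint(g, axis):
    gm = np.moveaxis(g, axis, -1)
    ge = gm[..., 0::2]
    go = gm[..., 1::2]
    d = 0.75 * (ge + go)
    # adjoint of the left-neighbour reads
    d[..., :-1] += 0.25 * ge[..., 1:]
    d[..., 0] += 0.25 * ge[..., 0]
    # adjoint of the right-neighbour reads
    d[..., 1:] += 0.25 * go[..., :-1]
    d[..., -1] += 0.25 * go[..., -1]
    return np.moveaxis(d, -1, axis)


def upsample2(x: Tensor) -> Tensor:
    """Factor-2 trilinear upsampling along the three trailing axes
    (half-voxel aligned: output centres interleave input centres)."""
    y = x.data
    for ax in (1, 2, 3):
        y = _up1d(y, ax)
    out = _result(y.astype(x.dtype), (x,))
    if out.requires_grad:
        def bw(g):
            if x.requires_grad:
                d = g
                for ax in (3, 2, 1):
                    d = _up1d_adjoint(d, ax)
                x._accumulate(d.astype(x.dtype))
        out._backward = bw
    return out


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor,
              running_mean, running_var, training: bool,
              momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel normalisation over the spatial axes (batch size one).

    ``running_mean``/``running_var`` are plain arrays mutated in place during
    training and used as fixed statistics in evaluation mode.
    """
    c = x.data.shape[0]
    xd = x.data.reshape(c, -1)
    if training:
        mu = xd.mean(axis=1)
        var = xd.var(axis=1)
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mu
        running_var *= (1.0 - momentum)
        running_var += momentum * var
    else:
        mu = running_mean.astype(x.dtype)
        var = running_var.astype(x.dtype)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu[:, None]) * inv[:, None]
    y = (gamma.data[:, None] * xhat + beta.data[:, None]).reshape(x.shape)
    out = _result(y.astype(x.dtype), (x, gamma, beta))
    if out.requires_grad:
        def bw(g):
            gf = g.reshape(c, -1)
            if beta.requires_grad:
                beta._accumulate(gf.sum(axis=1))
            if gamma.requires_grad:
                gamma._accumulate((gf * xhat).sum(axis=1))
            if x.requires_grad:
                gxhat = gf * gamma.data[:, None]
                if training:
                    n = xhat.shape[1]
                    dx = (gxhat - gxhat.mean(axis=1, keepdims=True)
                          - xhat * (gxhat * xhat).mean(axis=1, keepdims=True))
                    dx *= inv[:, None]
                else:
                    dx = gxhat * inv[:, None]
                x._accumulate(dx.reshape(x.shape).astype(x.dtype))
        out._backward = bw
    return out


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over axis 0 (the class-channel axis)."""
    z = x.data - x.data.max(axis=0, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=0, keepdims=True)
    out = _result(s.astype(x.dtype), (x,))
    if out.requires_grad:
        def bw(g):
            if x.requires_grad:
                dot = (g * s).sum(axis=0, keepdims=True)
                x._accumulate((s * (g - dot)).astype(x.dtype))
        out._backward = bw
    return out
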