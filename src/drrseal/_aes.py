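"""AES block cipher with CBC mode and PKCS#7 padding, in pure Python.

The cipher is the FIPS-197 algorithm for 128/192/256-bit keys.  Nothing here
is novel: the S-box is generated from its algebraic definition (multiplicative
inverse in GF(2^8) modulo x^8+x^4+x^3+x+1, followed by the fixed affine map)
rather than transcribed, and the whole module is pinned to the FIPS-197 and
NIST SP 800-38A known-answer vectors in the test suite.

Performance is adequate for the kilobyte-sized DRR blocks this package
encrypts; this is not a general-purpose cryptography library and offers no
constant-time guarantees.
"""

from __future__ import annotations

import hashlib
import hmac

__all__ = [
    "encrypt_block",
    "decrypt_block",
    "expand_key",
    "cbc_encrypt",
    "cbc_decrypt",
    "pkcs7_pad",
    "pkcs7_unpad",
    "derive_key",
    "PaddingError",
]


class PaddingError(ValueError):
    """PKCS#7 padding is invalid after decryption (wrong key or corruption)."""


# ---------------------------------------------------------------- GF(2^8)

def _gmul(a: int, b: int) -> int:
    """Multiply in GF(2^8) modulo the AES polynomial 0x11b."""
    p = 0
    while b:
        if b & 1:
            p ^= a
        a <<= 1
        if a & 0x100:
            a ^= 0x11B
        b >>= 1
    return p


def _ginv(a: int) -> int:
    # a^254 = a^-1 in GF(2^8)*; 0 maps to 0 by AES convention.
    if a == 0:
        return 0
    r = 1
    x, e = a, 254
    while e:
        if e & 1:
            r = _gmul(r, x)
        x = _gmul(x, x)
        e >>= 1
    return r


def _build_sbox() -> tuple[bytes, bytes]:
    sbox = bytearray(256)
    for i in range(256):
        b = _ginv(i)
        s = 0x63
        for shift in range(5):  # b ^ b<<<1 ^ b<<<2 ^ b<<<3 ^ b<<<4
            s ^= ((b << shift) | (b >> (8 - shift))) & 0xFF
        sbox[i] = s
    inv = bytearray(256)
    for i, s in enumerate(sbox):
        inv[s] = i
    return bytes(sbox), bytes(inv)


_SBOX, _INV_SBOX = _build_sbox()

# xtime-style multiplication tables used by (Inv)MixColumns.
_MUL = {n: bytes(_gmul(x, n) for x in range(256)) for n in (2, 3, 9, 11, 13, 14)}


# ------------------------------------------------------------ key schedule

def expand_key(key: bytes) -> list[list[int]]:
    """FIPS-197 key expansion; returns one flat 16-int round key per round."""
    nk = len(key) // 4
    if len(key) not in (16, 24, 32):
        raise ValueError("AES key must be 16, 24 or 32 bytes")
    nr = nk + 6
    words = [list(key[4 * i : 4 * i + 4]) for i in range(nk)]
    rcon = 1
    for i in range(nk, 4 * (nr + 1)):
        temp = list(words[i - 1])
        if i % nk == 0:
            temp = temp[1:] + temp[:1]
            temp = [_SBOX[b] for b in temp]
            temp[0] ^= rcon
            rcon = _gmul(rcon, 2)
        elif nk > 6 and i % nk == 4:
            temp = [_SBOX[b] for b in temp]
        words.append([a ^ b for a, b in zip(words[i - nk], temp)])
    round_keys = []
    for r in range(nr + 1):
        rk: list[int] = []
        for w in words[4 * r : 4 * r + 4]:
            rk.extend(w)
        round_keys.append(rk)
    return round_keys


# ------------------------------------------------------------ block cipher
#
# State layout: flat list s with s[4*c + r] = state column c, row r, which is
# exactly the byte order of the input block.

_SHIFT = [0, 5, 10, 15, 4, 9, 14, 3, 8, 13, 2, 7, 12, 1, 6, 11]
_INV_SHIFT = [0, 13, 10, 7, 4, 1, 14, 11, 8, 5, 2, 15, 12, 9, 6, 3]


def encrypt_block(block: bytes, round_keys: list[list[int]]) -> bytes:
    if len(block) != 16:
        raise ValueError("AES block must be 16 bytes")
    nr = len(round_keys) - 1
    m2, m3 = _MUL[2], _MUL[3]
    s = [b ^ k for b, k in zip(block, round_keys[0])]
    for rnd in range(1, nr):
        # SubBytes + ShiftRows fused
        t = [_SBOX[s[_SHIFT[i]]] for i in range(16)]
        rk = round_keys[rnd]
        s = [0] * 16
        for c in range(0, 16, 4):
            a0, a1, a2, a3 = t[c], t[c + 1], t[c + 2], t[c + 3]
            s[c] = m2[a0] ^ m3[a1] ^ a2 ^ a3 ^ rk[c]
            s[c + 1] = a0 ^ m2[a1] ^ m3[a2] ^ a3 ^ rk[c + 1]
            s[c + 2] = a0 ^ a1 ^ m2[a2] ^ m3[a3] ^ rk[c + 2]
            s[c + 3] = m3[a0] ^ a1 ^ a2 ^ m2[a3] ^ rk[c + 3]
    rk = round_keys[nr]
    return bytes(_SBOX[s[_SHIFT[i]]] ^ rk[i] for i in range(16))


def decrypt_block(block: bytes, round_keys: list[list[int]]) -> bytes:
    if len(block) != 16:
        raise ValueError("AES block must be 16 bytes")
    nr = len(round_keys) - 1
    m9, m11, m13, m14 = _MUL[9], _MUL[11], _MUL[13], _MUL[14]
    s = [b ^ k for b, k in zip(block, round_keys[nr])]
    for rnd in range(nr - 1, 0, -1):
        t = [_INV_SBOX[s[_INV_SHIFT[i]]] ^ round_keys[rnd][i] for i in range(16)]
        s = [0] * 16
        for c in range(0, 16, 4):
            a0, a1, a2, a3 = t[c], t[c + 1], t[c + 2], t[c + 3]
            s[c] = m14[a0] ^ m11[a1] ^ m13[a2] ^ m9[a3]
            s[c + 1] = m9[a0] ^ m14[a1] ^ m11[a2] ^ m13[a3]
            s[c + 2] = m13[a0] ^ m9[a1] ^ m14[a2] ^ m11[a3]
            s[c + 3] = m11[a0] ^ m13[a1] ^ m9[a2] ^ m14[a3]
    rk = round_keys[0]
    return bytes(_INV_SBOX[s[_INV_SHIFT[i]]] ^ rk[i] for i in range(16))


# ------------------------------------------------------------------- modes

def pkcs7_pad(data: bytes, block_size: int = 16) -> bytes:
    n = block_size - (len(data) % block_size)
    return data + bytes([n]) * n


def pkcs7_unpad(data: bytes, block_size: int = 16) -> bytes:
    if not data or len(data) % block_size:
        raise PaddingError("ciphertext length is not a multiple of the block size")
    n = data[-1]
    if not 1 <= n <= block_size or data[-n:] != bytes([n]) * n:
        raise PaddingError("invalid PKCS#7 padding")
    return data[:-n]


def cbc_encrypt(key: bytes, iv: bytes, plaintext: bytes) -> bytes:
    """AES-CBC encrypt with PKCS#7 padding applied to *plaintext*."""
    if len(iv) != 16:
        raise ValueError("IV must be 16 bytes")
    rks = expand_key(key)
    data = pkcs7_pad(plaintext)
    out = bytearray()
    prev = iv
    for i in range(0, len(data), 16):
        blk = bytes(a ^ b for a, b in zip(data[i : i + 16], prev))
        prev = encrypt_block(blk, rks)
        out.extend(prev)
    return bytes(out)


def cbc_decrypt(key: bytes, iv: bytes, ciphertext: bytes) -> bytes:
    """AES-CBC decrypt and strip PKCS#7 padding; raises PaddingError."""
    if len(iv) != 16:
        raise ValueError("IV must be 16 bytes")
    if not ciphertext or len(ciphertext) % 16:
        raise PaddingError("ciphertext length is not a multiple of 16")
    rks = expand_key(key)
    out = bytearray()
    prev = iv
    for i in range(0, len(ciphertext), 16):
        blk = ciphertext[i : i + 16]
        out.extend(a ^ b for a, b in zip(decrypt_block(blk, rks), prev))
        prev = blk
    return pkcs7_unpad(bytes(out))


def derive_key(passphrase: str, salt: bytes, iterations: int, length: int = 32) -> bytes:
    """PBKDF2-HMAC-SHA256 key derivation for the user passphrase."""
    if not passphrase:
        raise ValueError("passphrase must be non-empty")
    if iterations < 1:
        raise ValueError("iterations must be positive")
    return hashlib.pbkdf2_hmac("sha256", passphrase.encode("utf-8"), salt, iterations, length)


def constant_time_eq(a: bytes, b: bytes) -> bool:
    return hmac.compare_digest(a, b)
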