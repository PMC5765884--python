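# Default letter inventory: the stimulus-construction sets used throughout
# the factorial reading-aloud designs.  Override any key and load with
# LetterInventory.from_file.
short_vowels: [a, e, o, u]
long_vowel_digraphs: [ai, ea, ee, oa, oo, ou]
prefix_pairs:
  - [de, do]
  - [mis, mes]
  - [pre, pra]
  - [re, ro]
stress_taking_suffixes: [een, ique, oo]
plain_suffixes: [er, ow, le, ish, ness, ful, less, ing, ed, ly, es, en]
legal_onsets: [b, c, d, f, g, h, j, k, l, m, n, p, q, r, s, t, v, w, x, z,
               bl, br, cl, cr, dr, fl, fr, gl, gr, pl, pr,
               sc, sk, sl, sm, sn, sp, st, str, tr, th, sh, ch, wh, ph]
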