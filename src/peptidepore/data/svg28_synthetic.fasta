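>SVG28 synthetic stand-in 28-mer beta-hairpin (Ser at 5/11/17/23)
GVLVSVGVWVSVNPDGSVWVGVSVLVVG
>SVG28-D4 synthetic stand-in, S5D/S11D/S17D/S23D
GVLVDVGVWVDVNPDGDVWVGVDVLVVG
>SVG28-N4 synthetic stand-in, S5N/S11N/S17N/S23N
GVLVNVGVWVNVNPDGNVWVGVNVLVVG
>SVG28-D2 synthetic stand-in, S5D/S23D
GVLVDVGVWVSVNPDGSVWVGVDVLVVG
>SVG28-N2 synthetic stand-in, S5N/S23N
GVLVNVGVWVSVNPDGSVWVGVNVLVVG
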