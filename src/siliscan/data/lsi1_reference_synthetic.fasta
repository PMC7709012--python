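>lsi1_reference_synthetic constructed channel-type SIT scaffold (synthetic)
MKGDQRTKQLIVILFLIVFLIILIILLLFLDQSRQYTSKRKHKDTILVLIVLVIIIVVVG
ILIILLRYSNPAGKDDDEEVAALLIIVLVIFVIAVIVVLFKQQRDSKKETDDTDQFLVIL
AIIFALAVVAILILFVRETSKSSGESYKQSIALIVAIIFIIAFLSIFLLLFHEDGKEESR
NPAEGDTKKKRKQEIILLILLVLLLLALVVLLFLIDRTSGSTDSKGGKRSQTEKDQQQKD
QDTSREERTEKTKKKSEEYSKREKSEKRSSTSDQRGQDTRKRTTHDDEQQRKEKKHSR
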