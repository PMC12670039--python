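subject,signal,mi_left,mi_right,mi_combined
S00,osc_alpha,0.9539241195870386,-1.2762215908013765,2.230145710388415
S00,ap_alpha,0.3375247252134273,-0.30806716212187457,0.6455918873353019
S00,mix_alpha,0.5607321409069538,-0.7118488196781729,1.2725809605851266
S00,slope,0.030716743109956417,0.017335832414482246,0.01338091069547417
S00,intercept,0.17819691370736393,-0.09680805464708658,0.27500496835445054
S01,osc_alpha,0.8484940104393084,-1.159202085581369,2.0076960960206773
S01,ap_alpha,0.27069600865975174,-0.303774632179932,0.5744706408396838
S01,mix_alpha,0.5457940737227117,-0.6933373500794566,1.2391314238021685
S01,slope,0.030706280855976993,0.03198534232727985,-0.0012790614713028559
S01,intercept,0.16582606324029464,-0.07190281435908802,0.23772887759938266
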