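# structural alphabet: 27 letters x 4 descriptors (d13 d14 d24 volume); source='kmeans on synthetic helix-loop-helix windows'
5.336249053860383285e+00 4.002800730069091983e+00 5.187809757668828681e+00 3.456423977849905071e+00
6.169971320351515409e+00 4.760450387502115355e+00 4.946024086880776771e+00 -2.186720459438390218e+00
5.414938050660092372e+00 5.054008037774141648e+00 5.429019130137870519e+00 7.170460838016633254e+00
5.009013676168476259e+00 5.559885749707412117e+00 4.892340930847205449e+00 -7.763899942805298160e+00
4.231073303327610446e+00 5.897988383904825938e+00 6.427426931165108215e+00 -5.082308759963082956e+00
4.546769124623160963e+00 6.156293652222995405e+00 7.126742215335186259e+00 -1.674558371817415070e+00
5.737898797323101263e+00 6.499720515413396349e+00 4.309365528842647564e+00 6.749829645418690127e+00
5.175420291412516249e+00 6.732802147352263233e+00 5.499904824158985406e+00 8.319969434376675466e+00
5.502589597712862712e+00 6.754405743446932675e+00 6.826267801387909451e+00 2.918731170533590991e+00
6.595613458178177346e+00 6.891623850619276404e+00 4.473143500435290854e+00 -5.265005654332207463e+00
7.067087171212675933e+00 7.020456445718910921e+00 4.498952585272598448e+00 1.063417144745729237e+00
6.878790547665357025e+00 7.218276579655231728e+00 4.478885492241755806e+00 4.118141467361326136e+00
4.636067806513198164e+00 7.368820380163835893e+00 6.573206672360552894e+00 5.199036499635089292e+00
4.648766497052846169e+00 7.419410147229358543e+00 7.174377296410728633e+00 1.129578042277200378e+00
6.999856900062283671e+00 7.486298800054236757e+00 4.623113490988420615e+00 -2.156207948788227746e+00
5.683583855054684442e+00 7.703211280741239619e+00 5.986273142501557842e+00 -7.256008612296128035e+00
4.843729052095122611e+00 7.716810692068280630e+00 4.882282119195322956e+00 -2.237796917767476579e+00
4.782990814985119243e+00 8.064834931597721024e+00 5.556722832049168836e+00 1.867116740781858963e+00
5.159817784146428998e+00 8.100604515030342512e+00 7.019151322562581008e+00 -3.659749581485884917e+00
6.311583859849581479e+00 8.352514426976803463e+00 6.180428933653443480e+00 6.387818986844806979e+00
5.675125411758766170e+00 8.696143372347835410e+00 7.212887474611571648e+00 -7.857320176875324247e-01
7.134783496327239405e+00 8.791965101752893474e+00 5.555372165012256502e+00 8.598586127496907205e-02
6.990209114545387514e+00 8.950470653877312444e+00 5.805638259252052791e+00 -3.275554681252983880e+00
6.461472541794075930e+00 9.055838374876275410e+00 6.656259341233409010e+00 -5.065377702378171421e+00
6.641780479494697076e+00 9.197641609241300031e+00 6.510264842793678675e+00 3.923854536681335325e+00
6.910280392648294523e+00 1.012073405385109304e+01 7.034636439981594158e+00 1.473386539105009163e+00
7.082475254656291241e+00 1.028452343757139431e+01 7.087391063475395825e+00 -1.388056889644368797e+00
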